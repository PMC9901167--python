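"""Compound featurization: ECFP4 fingerprints, Tanimoto similarity and
randomized baseline fingerprints.

ECFP4 is the extended-connectivity (Morgan) fingerprint of radius 2 hashed
into a fixed-width binary vector; bit assignment follows RDKit's Morgan
generator, the de-facto standard.  All similarity thresholds downstream are
on Tanimoto values, which are stable under any consistent bit mapping.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional

import numpy as np

from dtibench.errors import DimensionError, ParseError
from dtibench.io import FeatureTable


def ecfp4(smiles: str, width: int = 1024) -> np.ndarray:
    """1024-bit (by default) ECFP4 fingerprint of a SMILES string.

    Raises :class:`ParseError` naming the string when RDKit cannot parse it.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=width)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(width, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| over binary vectors; 0.0 when both are all-zero."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise DimensionError(f"fingerprint widths differ: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(fps_a: np.ndarray, fps_b: Optional[np.ndarray] = None) -> np.ndarray:
    """All-pairs Tanimoto between the rows of two binary matrices.

    Vectorized popcount path; identical results to the pairwise definition.
    """
    A = np.asarray(fps_a, dtype=bool).astype(np.float64)
    B = A if fps_b is None else np.asarray(fps_b, dtype=bool).astype(np.float64)
    inter = A @ B.T
    ones_a = A.sum(axis=1)[:, None]
    ones_b = B.sum(axis=1)[None, :]
    union = ones_a + ones_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


def random_fingerprint(width: int = 1024, p_one: float = 0.1,
                       rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """i.i.d. Bernoulli(p_one) binary vector emulating the bit density of
    real ECFP4 fingerprints (about 10% ones)."""
    if rng is None:
        rng = np.random.default_rng()
    if not 0.0 <= p_one <= 1.0:
        raise ValueError(f"p_one must be in [0,1], got {p_one}")
    return (rng.random(width) < p_one).astype(np.uint8)


def fingerprint_table(fingerprints: Mapping[str, np.ndarray]) -> FeatureTable:
    """Wrap id -> fingerprint vectors as a compound FeatureTable."""
    return FeatureTable({k: np.asarray(v, dtype=float) for k, v in fingerprints.items()},
                        kind="compound")


def featurize_smiles(smiles_map: Mapping[str, str], width: int = 1024) -> FeatureTable:
    """ECFP4-featurize a compound_id -> SMILES map into a FeatureTable."""
    return fingerprint_table({cid: ecfp4(smi, width) for cid, smi in smiles_map.items()})
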