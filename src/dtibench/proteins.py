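"""Protein sequence descriptors: dde, taap, spmap and the random200 baseline.

dde (dipeptide deviation from expected mean) standardizes observed dipeptide
fractions against the mean and variance expected from standard-genetic-code
codon usage.  taap (total amino acid properties) sums ten physicochemical
scales over the residues of a sequence.  spmap (subsequence profile map)
represents a sequence by the distribution of its k-mers over BLOSUM62-scored
k-mer cluster centers fitted on a reference sequence set.  random200 is a
200-dimensional uniform-noise baseline used to probe whether a model exploits
protein information at all.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from dtibench.errors import InputError
from dtibench.io import CANONICAL_RESIDUES, FeatureTable, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Sense-codon counts of the standard genetic code (61 sense codons total).
CODON_COUNTS: Dict[str, int] = {
    "A": 4, "R": 6, "N": 2, "D": 2, "C": 2, "Q": 2, "E": 2, "G": 4, "H": 2,
    "I": 3, "L": 6, "K": 2, "M": 1, "F": 2, "P": 4, "S": 6, "T": 4, "W": 1,
    "Y": 2, "V": 4,
}

DIPEPTIDES: List[str] = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
# lexicographic AA..YY given AMINO_ACIDS is sorted
assert DIPEPTIDES == sorted(DIPEPTIDES)

# Ten AAindex-style physicochemical scales summed by taap.  Accessions
# (documented choices, see docs/methods.md):
#   CIDH920105 normalized average hydrophobicity scale
#   BHAR880101 average flexibility indices
#   CHAM820101 polarizability parameter
#   CHAM820102 free energy of solution in water
#   CHOC760101 residue accessible surface area in tripeptide
#   BIGC670101 residue volume
#   CHAM810101 steric parameter
#   DAYM780201 relative mutability
#   HOPT810101 hydrophilicity value
#   KRIW790103 side chain volume
TAAP_PROPERTY_TABLE: Dict[str, Dict[str, float]] = {
    "hydrophobicity_CIDH920105": {
        "A": 0.02, "R": -0.42, "N": -0.77, "D": -1.04, "C": 0.77, "Q": -1.10,
        "E": -1.14, "G": -0.80, "H": 0.26, "I": 1.81, "L": 1.14, "K": -0.41,
        "M": 1.00, "F": 1.35, "P": -0.09, "S": -0.97, "T": -0.77, "W": 1.71,
        "Y": 1.11, "V": 1.13,
    },
    "flexibility_BHAR880101": {
        "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346, "Q": 0.493,
        "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462, "L": 0.365, "K": 0.466,
        "M": 0.295, "F": 0.314, "P": 0.509, "S": 0.507, "T": 0.444, "W": 0.305,
        "Y": 0.420, "V": 0.386,
    },
    "polarizability_CHAM820101": {
        "A": 0.046, "R": 0.291, "N": 0.134, "D": 0.105, "C": 0.128, "Q": 0.180,
        "E": 0.151, "G": 0.000, "H": 0.230, "I": 0.186, "L": 0.186, "K": 0.219,
        "M": 0.221, "F": 0.290, "P": 0.131, "S": 0.062, "T": 0.108, "W": 0.409,
        "Y": 0.298, "V": 0.140,
    },
    "free_energy_water_CHAM820102": {
        "A": -0.368, "R": -1.030, "N": 0.000, "D": 2.060, "C": 4.530, "Q": 0.731,
        "E": 1.770, "G": -0.525, "H": 0.000, "I": 0.791, "L": 1.070, "K": 0.000,
        "M": 0.656, "F": 1.060, "P": -2.240, "S": -0.524, "T": 0.000, "W": 1.600,
        "Y": 4.910, "V": 0.401,
    },
    "asa_tripeptide_CHOC760101": {
        "A": 115.0, "R": 225.0, "N": 160.0, "D": 150.0, "C": 135.0, "Q": 180.0,
        "E": 190.0, "G": 75.0, "H": 195.0, "I": 175.0, "L": 170.0, "K": 200.0,
        "M": 185.0, "F": 210.0, "P": 145.0, "S": 115.0, "T": 140.0, "W": 255.0,
        "Y": 230.0, "V": 155.0,
    },
    "residue_volume_BIGC670101": {
        "A": 52.6, "R": 109.1, "N": 75.7, "D": 68.4, "C": 68.3, "Q": 89.7,
        "E": 84.7, "G": 36.3, "H": 91.9, "I": 102.0, "L": 102.0, "K": 105.1,
        "M": 97.7, "F": 113.9, "P": 73.6, "S": 54.9, "T": 71.2, "W": 135.4,
        "Y": 116.2, "V": 85.1,
    },
    "steric_parameter_CHAM810101": {
        "A": 0.52, "R": 0.68, "N": 0.76, "D": 0.76, "C": 0.62, "Q": 0.68,
        "E": 0.68, "G": 0.00, "H": 0.70, "I": 1.02, "L": 0.98, "K": 0.68,
        "M": 0.78, "F": 0.70, "P": 0.36, "S": 0.53, "T": 0.50, "W": 0.70,
        "Y": 0.70, "V": 0.76,
    },
    "relative_mutability_DAYM780201": {
        "A": 100.0, "R": 65.0, "N": 134.0, "D": 106.0, "C": 20.0, "Q": 93.0,
        "E": 102.0, "G": 49.0, "H": 66.0, "I": 96.0, "L": 40.0, "K": 56.0,
        "M": 94.0, "F": 41.0, "P": 56.0, "S": 120.0, "T": 97.0, "W": 18.0,
        "Y": 41.0, "V": 74.0,
    },
    "hydrophilicity_HOPT810101": {
        "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
        "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
        "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
        "Y": -2.3, "V": -1.5,
    },
    "side_chain_volume_KRIW790103": {
        "A": 27.5, "R": 105.0, "N": 58.7, "D": 40.0, "C": 44.6, "Q": 80.7,
        "E": 62.0, "G": 0.0, "H": 79.0, "I": 93.5, "L": 93.5, "K": 100.0,
        "M": 94.1, "F": 115.5, "P": 41.9, "S": 29.3, "T": 51.3, "W": 145.5,
        "Y": 117.3, "V": 71.5,
    },
}


def _check_canonical(sequence: str) -> None:
    bad = set(sequence) - CANONICAL_RESIDUES
    if bad:
        raise InputError(f"non-canonical residue(s) {sorted(bad)} in sequence")


# ---------------------------------------------------------------------------
# dde
# ---------------------------------------------------------------------------

def dde_components(sequence: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Dc, Tm, Tv) for all 400 dipeptides in lexicographic order.

    Dc_i = count(dipeptide i) / (N - 1)
    Tm_i = (C_a / 61) * (C_b / 61) with C the sense-codon counts
    Tv_i = Tm_i * (1 - Tm_i) / (N - 1)
    """
    if len(sequence) < 2:
        raise InputError("dde requires a sequence of length >= 2")
    _check_canonical(sequence)
    n_dipep = len(sequence) - 1
    counts = np.zeros(400)
    index = {dp: i for i, dp in enumerate(DIPEPTIDES)}
    for i in range(n_dipep):
        counts[index[sequence[i:i + 2]]] += 1
    dc = counts / n_dipep
    tm = np.array(
        [(CODON_COUNTS[dp[0]] / 61.0) * (CODON_COUNTS[dp[1]] / 61.0) for dp in DIPEPTIDES]
    )
    tv = tm * (1.0 - tm) / n_dipep
    return dc, tm, tv


def dde(sequence: str) -> np.ndarray:
    """400-dimensional dipeptide deviation from expected mean:
    DDE_i = (Dc_i - Tm_i) / sqrt(Tv_i)."""
    dc, tm, tv = dde_components(sequence)
    return (dc - tm) / np.sqrt(tv)


# ---------------------------------------------------------------------------
# taap
# ---------------------------------------------------------------------------

def taap(sequence: str,
         table: Optional[Mapping[str, Mapping[str, float]]] = None) -> np.ndarray:
    """Sum each physicochemical property over the residues of a sequence.

    Returns one entry per property (10 with the default table).
    """
    if table is None:
        table = TAAP_PROPERTY_TABLE
    _check_canonical(sequence)
    out = np.empty(len(table))
    for j, (name, scale) in enumerate(table.items()):
        try:
            out[j] = sum(scale[res] for res in sequence)
        except KeyError as exc:
            raise InputError(f"property {name!r} lacks residue {exc.args[0]!r}") from exc
    return out


# ---------------------------------------------------------------------------
# spmap
# ---------------------------------------------------------------------------

def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def blosum_kmer_score(a: str, b: str, matrix=None) -> float:
    """Ungapped position-wise BLOSUM62 sum between two equal-length k-mers."""
    if matrix is None:
        matrix = _blosum62()
    if len(a) != len(b):
        raise InputError("k-mers must have equal length")
    return float(sum(matrix[x, y] for x, y in zip(a, b)))


@dataclass
class SpmapModel:
    """Fitted subsequence-profile-map: k-mer cluster centers scored by BLOSUM62."""

    k: int
    centers: List[str]

    def __post_init__(self):
        if not self.centers:
            raise InputError("spmap model requires at least one center")
        if any(len(c) != self.k for c in self.centers):
            raise InputError("all centers must have length k")


def _kmers(sequence: str, k: int) -> List[str]:
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


def spmap_fit(sequences: Iterable[str], k: int = 5,
              score_threshold: float = 8.0,
              max_centers: Optional[int] = None) -> SpmapModel:
    """Greedy leader clustering of all k-mers in the input set.

    k-mers are visited in descending frequency (ties lexicographic); a k-mer
    becomes a new center when its best BLOSUM62 score against every existing
    center is below ``score_threshold``, until ``max_centers`` is reached.
    Deterministic for a fixed input set.
    """
    counts: Dict[str, int] = {}
    for seq in sequences:
        _check_canonical(seq)
        for km in _kmers(seq, k):
            counts[km] = counts.get(km, 0) + 1
    if not counts:
        raise InputError(f"no k-mer of length {k} extractable from the input")
    matrix = _blosum62()
    ordered = sorted(counts, key=lambda km: (-counts[km], km))
    centers: List[str] = []
    for km in ordered:
        if max_centers is not None and len(centers) >= max_centers:
            break
        best = max((blosum_kmer_score(km, c, matrix) for c in centers), default=-np.inf)
        if best < score_threshold:
            centers.append(km)
    if not centers:
        centers.append(ordered[0])
    return SpmapModel(k=k, centers=centers)


def spmap_transform(model: SpmapModel, sequence: str) -> np.ndarray:
    """Distribution of a sequence's k-mers over the model's centers.

    Each k-mer goes to its best-scoring center (ties -> lexicographically
    smallest center); the vector is normalized to sum to 1.
    """
    if len(sequence) < model.k:
        raise InputError(
            f"sequence of length {len(sequence)} shorter than k={model.k}"
        )
    _check_canonical(sequence)
    matrix = _blosum62()
    order = sorted(range(len(model.centers)), key=lambda i: model.centers[i])
    counts = np.zeros(len(model.centers))
    kms = _kmers(sequence, model.k)
    for km in kms:
        best_idx = None
        best_score = -np.inf
        for i in order:  # lexicographic center order makes ties deterministic
            s = blosum_kmer_score(km, model.centers[i], matrix)
            if s > best_score:
                best_score = s
                best_idx = i
        counts[best_idx] += 1
    return counts / len(kms)


# ---------------------------------------------------------------------------
# random200
# ---------------------------------------------------------------------------

def random200(rng: np.random.Generator) -> np.ndarray:
    """200 i.i.d. Uniform(0,1) values — the protein-side noise baseline."""
    return rng.random(200)


# ---------------------------------------------------------------------------
# batch featurization
# ---------------------------------------------------------------------------

def featurize_proteins(records: Sequence[ProteinRecord], method: str = "dde",
                       seed: int = 0, **kwargs) -> FeatureTable:
    """Compute a named descriptor for every protein and return a FeatureTable.

    ``method`` is one of dde, taap, spmap, random200.  spmap fits its centers
    on the input set itself unless a fitted ``model`` is passed.
    """
    if method == "dde":
        vectors = {r.protein_id: dde(r.sequence) for r in records}
    elif method == "taap":
        vectors = {r.protein_id: taap(r.sequence, kwargs.get("table")) for r in records}
    elif method == "spmap":
        model = kwargs.get("model")
        if model is None:
            model = spmap_fit(
                [r.sequence for r in records],
                k=kwargs.get("k", 5),
                score_threshold=kwargs.get("score_threshold", 8.0),
                max_centers=kwargs.get("max_centers"),
            )
        vectors = {r.protein_id: spmap_transform(model, r.sequence) for r in records}
    elif method == "random200":
        rng = np.random.default_rng(seed)
        vectors = {r.protein_id: random200(rng) for r in records}
    else:
        raise InputError(f"unknown protein featurization method {method!r}")
    return FeatureTable(vectors, kind="protein")
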