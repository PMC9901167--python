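"""Synthetic benchmark generator.

Emulates the statistical structure of curated bioactivity datasets without
any download: compound families with controlled Tanimoto structure
(family-template fingerprints plus per-bit noise), protein clusters with
controlled sequence divergence (ancestor sequences plus point mutations),
and bioactivities with additive family/cluster/interaction effects, Gaussian
noise, and optional floor-censoring (the Davis-style artifact where
unobserved activities are recorded exactly at the maximum assayed dose,
pKd = 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple
import warnings

import numpy as np

from dtibench.errors import InputError
from dtibench.io import (
    BioactivityRecord,
    BioactivityTable,
    ClusterMap,
    CompoundRecord,
    ProteinRecord,
)
from dtibench.proteins import AMINO_ACIDS

# Small fixture of real drug-like SMILES used solely to exercise the
# SMILES -> ECFP4 path in tests; synthetic compounds otherwise carry
# fingerprints directly.
FIXTURE_SMILES: Dict[str, str] = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "naproxen": "COc1ccc2cc(ccc2c1)C(C)C(=O)O",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "ethanol": "CCO",
    "acetone": "CC(C)=O",
    "glycine": "NCC(=O)O",
    "alanine": "CC(N)C(=O)O",
    "nicotine": "CN1CCCC1c1cccnc1",
    "imatinib": "Cc1ccc(cc1Nc1nccc(n1)-c1cccnc1)NC(=O)c1ccc(cc1)CN1CCN(C)CC1",
    "sulfanilamide": "Nc1ccc(cc1)S(N)(=O)=O",
    "warfarin": "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "diazepam": "CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1",
    "tamoxifen": "CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1",
    "quercetin": "Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O",
    "curcumin": "COc1cc(/C=C/C(=O)CC(=O)/C=C/c2ccc(O)c(OC)c2)ccc1O",
    "genistein": "Oc1ccc(cc1)-c1coc2cc(O)cc(O)c2c1=O",
    "econazole": "Clc1ccc(COC(Cn2ccnc2)c2ccc(Cl)cc2Cl)cc1",
    "miconazole": "Clc1ccc(COC(Cn2ccnc2)c2ccc(Cl)cc2Cl)c(Cl)c1",
    "clotrimazole": "Clc1ccccc1C(c1ccccc1)(c1ccccc1)n1ccnc1",
    "amiodarone": "CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1",
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic benchmark.

    Defaults produce a desk-scale dataset with clear within- vs
    between-family similarity separation and effect sizes large enough,
    relative to measurement noise, that split difficulty ordering is
    observable.

    ``density`` is the overall expected fraction of (compound, protein)
    pairs measured.  ``assay_bias`` is a Gamma shape parameter (mean held
    at 1) that concentrates measurements into preferred (family, cluster)
    cells, mimicking how chemical series are assayed against related target
    subsets; small values give a blocky, modular bioactivity network, and
    ``assay_bias = 0`` disables the bias (uniform measurement).
    """

    n_compound_families: int = 30
    compounds_per_family: int = 8
    fingerprint_bits: int = 1024
    bit_flip_prob: float = 0.01
    template_density: float = 0.1
    n_protein_clusters: int = 15
    proteins_per_cluster: int = 4
    seq_length: int = 200
    mutation_rate: float = 0.05
    activity_base: float = 6.5
    family_effect_sd: float = 0.8
    cluster_effect_sd: float = 0.8
    interaction_sd: float = 0.5
    noise_sd: float = 0.3
    censor_floor: Optional[float] = 5.0
    density: float = 0.25
    assay_bias: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("bit_flip_prob", "template_density", "mutation_rate", "density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0,1], got {v}")
        for name in ("family_effect_sd", "cluster_effect_sd", "interaction_sd",
                     "noise_sd", "assay_bias"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        for name in ("n_compound_families", "compounds_per_family", "fingerprint_bits",
                     "n_protein_clusters", "proteins_per_cluster", "seq_length"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def gen_compounds(cfg: SyntheticConfig) -> Tuple[List[CompoundRecord], Dict[str, str]]:
    """Compounds as noisy copies of per-family template fingerprints.

    Returns (records, compound_id -> family_id).  Deterministic given
    cfg.seed.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    records: List[CompoundRecord] = []
    family_map: Dict[str, str] = {}
    for f in range(cfg.n_compound_families):
        template = (rng.random(cfg.fingerprint_bits) < cfg.template_density)
        family_id = f"fam{f:03d}"
        for m in range(cfg.compounds_per_family):
            flips = rng.random(cfg.fingerprint_bits) < cfg.bit_flip_prob
            bits = np.logical_xor(template, flips).astype(np.uint8)
            cid = f"c{f:03d}_{m:03d}"
            records.append(CompoundRecord(cid, fingerprint=bits))
            family_map[cid] = family_id
    return records, family_map


def gen_proteins(cfg: SyntheticConfig) -> Tuple[List[ProteinRecord], ClusterMap]:
    """Proteins as point-mutated copies of per-cluster ancestor sequences."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    alphabet = np.array(list(AMINO_ACIDS))
    records: List[ProteinRecord] = []
    assignments: Dict[str, str] = {}
    for c in range(cfg.n_protein_clusters):
        ancestor = rng.choice(alphabet, size=cfg.seq_length)
        cluster_id = f"clu{c:03d}"
        for m in range(cfg.proteins_per_cluster):
            seq = ancestor.copy()
            mutate = rng.random(cfg.seq_length) < cfg.mutation_rate
            if mutate.any():
                seq[mutate] = rng.choice(alphabet, size=int(mutate.sum()))
            pid = f"p{c:03d}_{m:03d}"
            records.append(ProteinRecord(pid, "".join(seq)))
            assignments[pid] = cluster_id
    return records, ClusterMap(assignments)


def gen_bioactivities(
    compounds: List[CompoundRecord],
    family_map: Dict[str, str],
    proteins: List[ProteinRecord],
    cluster_map: ClusterMap,
    cfg: SyntheticConfig,
) -> BioactivityTable:
    """Sample a measured subset of (compound, protein) pairs with additive
    family/cluster/interaction effects and Gaussian noise.

    activity = base + family_effect + cluster_effect + interaction + noise,
    then floor-censored at cfg.censor_floor when set (values below the floor
    are recorded exactly at the floor, not dropped).

    The probability that a pair is measured is ``density`` on average but,
    with ``assay_bias > 0``, varies by (family, cluster) cell: cell weights
    are Gamma(assay_bias, 1/assay_bias) draws (mean 1), so small shapes
    concentrate measurements into few cells.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    families = sorted(set(family_map.values()))
    clusters = sorted(set(cluster_map.assignments.values()))
    fam_eff = dict(zip(families, rng.normal(0.0, cfg.family_effect_sd, len(families))))
    clu_eff = dict(zip(clusters, rng.normal(0.0, cfg.cluster_effect_sd, len(clusters))))
    inter_eff = {
        (f, c): e
        for (f, c), e in zip(
            ((f, c) for f in families for c in clusters),
            rng.normal(0.0, cfg.interaction_sd, len(families) * len(clusters)),
        )
    }
    cells = [(f, c) for f in families for c in clusters]
    if cfg.assay_bias > 0:
        weights = rng.gamma(cfg.assay_bias, 1.0 / cfg.assay_bias, len(cells))
    else:
        weights = np.ones(len(cells))
    measure_prob = {
        cell: min(1.0, cfg.density * w) for cell, w in zip(cells, weights)
    }
    triples = []
    for comp in compounds:
        fam = family_map[comp.compound_id]
        for prot in proteins:
            clu_key = cluster_map.cluster_of(prot.protein_id)
            if rng.random() >= measure_prob[(fam, clu_key)]:
                continue
            clu = clu_key
            act = (
                cfg.activity_base
                + fam_eff[fam]
                + clu_eff[clu]
                + inter_eff[(fam, clu)]
                + rng.normal(0.0, cfg.noise_sd)
            )
            if cfg.censor_floor is not None and act < cfg.censor_floor:
                act = cfg.censor_floor
            triples.append((comp.compound_id, prot.protein_id, act))
    if not triples:
        warnings.warn("density produced an empty bioactivity table", stacklevel=2)
    return BioactivityTable.from_pairs(triples)


@dataclass
class SyntheticDataset:
    """Bundle of everything one simulation run produces."""

    compounds: List[CompoundRecord]
    family_map: Dict[str, str]
    proteins: List[ProteinRecord]
    cluster_map: ClusterMap
    table: BioactivityTable
    config: SyntheticConfig

    def fingerprints(self) -> Dict[str, np.ndarray]:
        return {c.compound_id: c.fingerprint for c in self.compounds}


def generate(cfg: Optional[SyntheticConfig] = None) -> SyntheticDataset:
    """Run the full generator pipeline with one config."""
    if cfg is None:
        cfg = SyntheticConfig()
    compounds, family_map = gen_compounds(cfg)
    proteins, cluster_map = gen_proteins(cfg)
    table = gen_bioactivities(compounds, family_map, proteins, cluster_map, cfg)
    return SyntheticDataset(compounds, family_map, proteins, cluster_map, table, cfg)
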