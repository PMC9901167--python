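"""End-to-end synthetic benchmark runs.

Ties the generator, the three splitting strategies, PCM model fitting and
scoring into one reproducible call, so split-difficulty comparisons (how
much held-out performance drops from a random split to a dissimilar-compound
split to a fully-dissimilar split) and feature-baseline comparisons (real
descriptors vs random noise vectors) can be computed from a single config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from dtibench import graph as graph_mod
from dtibench import metrics as metrics_mod
from dtibench import models as models_mod
from dtibench import proteins as proteins_mod
from dtibench import splits as splits_mod
from dtibench import synthetic as synthetic_mod
from dtibench.compounds import fingerprint_table, random_fingerprint
from dtibench.errors import InputError
from dtibench.io import FeatureTable
from dtibench.splits import SplitResult

STRATEGIES = ("random", "dissimilar-compound", "fully-dissimilar")


@dataclass
class BenchmarkResult:
    """Held-out scores per splitting strategy for one seed."""

    seed: int
    scores: Dict[str, Dict[str, float]]  # strategy -> metric name -> value
    fold_sizes: Dict[str, Dict[str, int]]
    n_records: int


def make_splits(
    data: synthetic_mod.SyntheticDataset,
    test_fraction: float = 0.15,
    seed: int = 0,
    cc_threshold: float = 0.5,
    tolerance: float = 0.1,
    max_rounds: int = 10,
) -> Dict[str, SplitResult]:
    """The three harmonized splits of one synthetic dataset.

    The fully-dissimilar split is computed first; its discarded records are
    propagated to the random and dissimilar-compound splits so all three
    share an identical record universe.
    """
    table = data.table
    measured_fps = {
        cid: fp for cid, fp in data.fingerprints().items() if cid in table.compound_index
    }
    cc = graph_mod.compound_similarity_edges(measured_fps, threshold=cc_threshold)
    pp = [
        (a, b)
        for a, b in graph_mod.protein_similarity_edges(data.cluster_map)
        if a in table.protein_index and b in table.protein_index
    ]
    g = graph_mod.build_hetero_graph(table, cc, pp)
    fully = splits_mod.split_fully_dissimilar(
        g, test_fraction, seed=seed, tolerance=tolerance, max_rounds=max_rounds
    )
    rand = splits_mod.split_random(table, test_fraction, seed)
    dissim = splits_mod.split_dissimilar_compound(table, cc, test_fraction, seed)
    rand, dissim = splits_mod.harmonize_splits(fully, [rand, dissim])
    return {"random": rand, "dissimilar-compound": dissim, "fully-dissimilar": fully}


def _protein_features(
    data: synthetic_mod.SyntheticDataset, method: str, seed: int
) -> FeatureTable:
    return proteins_mod.featurize_proteins(data.proteins, method=method, seed=seed)


def _compound_features(
    data: synthetic_mod.SyntheticDataset, randomize: bool, seed: int
) -> FeatureTable:
    if not randomize:
        return fingerprint_table(data.fingerprints())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    width = data.config.fingerprint_bits
    return fingerprint_table(
        {c.compound_id: random_fingerprint(width, 0.1, rng) for c in data.compounds}
    )


def score_split(
    data: synthetic_mod.SyntheticDataset,
    split: SplitResult,
    protein_features: FeatureTable,
    compound_features: FeatureTable,
    mode: str = "pcm",
    seed: int = 0,
) -> Dict[str, float]:
    """Fit the PCM random forest on a split's train fold and score its test
    fold with the regression metric set (cutoff = training-median rule)."""
    if not split.train or not split.test:
        raise InputError("split has an empty fold")
    train_matrix = models_mod.assemble_pcm_matrix(
        data.table, protein_features, compound_features, mode=mode,
        record_ids=sorted(split.train),
    )
    test_matrix = models_mod.assemble_pcm_matrix(
        data.table, protein_features, compound_features, mode=mode,
        record_ids=sorted(split.test),
    )
    model = models_mod.train_rf_regressor(
        train_matrix, models_mod.ModelSpec(task="regression", seed=seed)
    )
    y_pred = models_mod.predict(model, test_matrix)
    cutoff = float(np.median(train_matrix.y))
    return metrics_mod.regression_report(
        metrics_mod.PredictionSet(test_matrix.y, y_pred), cutoff=cutoff
    )


def run_benchmark(
    cfg: Optional[synthetic_mod.SyntheticConfig] = None,
    seed: int = 0,
    test_fraction: float = 0.15,
    protein_method: str = "dde",
    random_compounds: bool = False,
    mode: str = "pcm",
    strategies: Sequence[str] = STRATEGIES,
) -> BenchmarkResult:
    """One full generate -> split -> train -> score cycle.

    ``protein_method='random200'`` together with ``random_compounds=True``
    reproduces the all-noise baseline whose held-out correlation should
    collapse to ~0 under the fully-dissimilar split.
    """
    if cfg is None:
        cfg = synthetic_mod.SyntheticConfig(seed=seed)
    else:
        cfg = synthetic_mod.SyntheticConfig(**{**cfg.to_dict(), "seed": seed})
    data = synthetic_mod.generate(cfg)
    all_splits = make_splits(data, test_fraction=test_fraction, seed=seed)
    pf = _protein_features(data, protein_method, seed)
    cf = _compound_features(data, random_compounds, seed)
    scores: Dict[str, Dict[str, float]] = {}
    fold_sizes: Dict[str, Dict[str, int]] = {}
    for name in strategies:
        split = all_splits[name]
        scores[name] = score_split(data, split, pf, cf, mode=mode, seed=seed)
        fold_sizes[name] = {
            "train": len(split.train),
            "test": len(split.test),
            "discarded": len(split.discarded),
        }
    return BenchmarkResult(
        seed=seed, scores=scores, fold_sizes=fold_sizes, n_records=len(data.table)
    )


def mean_scores(
    results: Sequence[BenchmarkResult], metric: str = "spearman"
) -> Dict[str, float]:
    """Mean of one metric per strategy over several benchmark runs."""
    out: Dict[str, List[float]] = {}
    for res in results:
        for strategy, rep in res.scores.items():
            out.setdefault(strategy, []).append(rep[metric])
    return {k: float(np.mean(v)) for k, v in out.items()}
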