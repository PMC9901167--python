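"""Model and dataset diagnostics.

Covers the applicability-domain k-NN analysis (mean similarity of each test
item to its k most similar training items), pairwise prediction-agreement
matrices between models, two-sample distribution-shift tests per feature
(Kolmogorov-Smirnov for continuous features, chi-square for binary bits),
pairwise-similarity histograms, and a thin seeded t-SNE wrapper for 2-D
exploration of feature spaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import scipy.stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from dtibench.compounds import tanimoto_matrix
from dtibench.errors import ConsistencyError, DimensionError, InputError
from dtibench.io import FeatureTable
from dtibench.metrics import PredictionSet, assign_activity_class


@dataclass
class ShiftReport:
    """Per-feature two-sample test results between train and test folds."""

    statistic: np.ndarray  # KS distance or chi-square value; NaN where skipped
    p_value: np.ndarray
    alpha: float
    skipped: List[int] = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        valid = ~np.isnan(self.p_value)
        return int(np.sum(self.p_value[valid] < self.alpha))


def knn_ad(
    test_items: FeatureTable,
    train_items: FeatureTable,
    k: int = 5,
    similarity: str = "tanimoto",
    matrix: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> Dict[str, float]:
    """Mean similarity of each test item to its k nearest training items.

    ``similarity`` is 'tanimoto' (binary fingerprints) or 'precomputed'
    (pass ``matrix`` as test_id -> train_id -> similarity).  With fewer than
    k training items the mean runs over all of them.
    """
    if len(train_items) == 0:
        raise InputError("empty training set")
    out: Dict[str, float] = {}
    if similarity == "tanimoto":
        sim = tanimoto_matrix(test_items.matrix(), train_items.matrix())
        for i, tid in enumerate(test_items.ids):
            row = np.sort(sim[i])[::-1]
            out[tid] = float(np.mean(row[: min(k, row.size)]))
    elif similarity == "precomputed":
        if matrix is None:
            raise InputError("precomputed similarity requires a matrix")
        for tid in test_items.ids:
            sims = sorted(
                (float(matrix[tid][trid]) for trid in train_items.ids), reverse=True
            )
            out[tid] = float(np.mean(sims[: min(k, len(sims))]))
    else:
        raise InputError(f"unknown similarity {similarity!r}")
    return out


def ad_report(
    knn_similarity: Mapping[str, float],
    abs_errors: Mapping[str, float],
    error_threshold: float = 0.5,
) -> Dict:
    """Join k-NN similarities with absolute errors; summary = fraction of
    records predicted within ``error_threshold`` pChEMBL units."""
    ids = sorted(knn_similarity)
    errs = np.array([abs_errors[i] for i in ids])
    return {
        "ids": ids,
        "mean_knn_similarity": np.array([knn_similarity[i] for i in ids]),
        "abs_error": errs,
        "fraction_within_threshold": float(np.mean(errs < error_threshold)),
    }


def prediction_agreement(preds_a: PredictionSet, preds_b: PredictionSet) -> float:
    """Percent of records whose two predictions fall in the same activity bin
    (the 6 pChEMBL classes), regardless of correctness."""
    if preds_a.n != preds_b.n:
        raise InputError("prediction sets differ in length")
    bins_a = assign_activity_class(preds_a.y_pred)
    bins_b = assign_activity_class(preds_b.y_pred)
    return float(np.mean(bins_a == bins_b) * 100.0)


def agreement_matrix(
    model_predictions: Mapping[str, PredictionSet]
) -> Tuple[List[str], np.ndarray, List[int]]:
    """All-pairs prediction agreement with an average-linkage leaf order.

    Returns (model names, percent matrix with a 100 diagonal, leaf order as
    indices into the name list).
    """
    names = list(model_predictions)
    if len(names) < 2:
        raise InputError("need at least 2 models")
    n0 = model_predictions[names[0]].n
    if any(model_predictions[m].n != n0 for m in names):
        raise ConsistencyError("models evaluated on different record universes")
    k = len(names)
    mat = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            a = prediction_agreement(
                model_predictions[names[i]], model_predictions[names[j]]
            )
            mat[i, j] = mat[j, i] = a
    dist = squareform(100.0 - mat, checks=False)
    order = [int(i) for i in leaves_list(average(dist))]
    return names, mat, order


def ks_shift(
    train_features: FeatureTable, test_features: FeatureTable, alpha: float = 0.01
) -> ShiftReport:
    """Per-feature two-sample Kolmogorov-Smirnov test (asymptotic p-values)
    between train and test continuous feature distributions."""
    if train_features.dimension != test_features.dimension:
        raise DimensionError("train and test feature dimensions differ")
    A = train_features.matrix()
    B = test_features.matrix()
    d = A.shape[1]
    stat = np.empty(d)
    pval = np.empty(d)
    for j in range(d):
        res = scipy.stats.ks_2samp(A[:, j], B[:, j], method="asymp")
        stat[j] = res.statistic
        pval[j] = res.pvalue
    return ShiftReport(stat, pval, alpha)


def chi2_shift(
    train_bits: FeatureTable, test_bits: FeatureTable, alpha: float = 0.001
) -> ShiftReport:
    """Per-bit chi-square test (no continuity correction) of the 2x2
    bit-value x fold contingency table.  Bits constant across both folds are
    skipped (statistic undefined) and listed in the report."""
    if train_bits.dimension != test_bits.dimension:
        raise DimensionError("train and test feature dimensions differ")
    A = train_bits.matrix().astype(int)
    B = test_bits.matrix().astype(int)
    d = A.shape[1]
    stat = np.full(d, np.nan)
    pval = np.full(d, np.nan)
    skipped: List[int] = []
    for j in range(d):
        ones_a, ones_b = int(A[:, j].sum()), int(B[:, j].sum())
        table = np.array(
            [[ones_a, A.shape[0] - ones_a], [ones_b, B.shape[0] - ones_b]]
        )
        if (table.sum(axis=0) == 0).any():
            skipped.append(j)
            continue
        res = scipy.stats.chi2_contingency(table, correction=False)
        stat[j] = res.statistic
        pval[j] = res.pvalue
    return ShiftReport(stat, pval, alpha, skipped=skipped)


def pairwise_similarity_histogram(
    items: FeatureTable,
    groups: Mapping[str, Sequence[str]],
    bins: int = 20,
    sample_fraction: float = 1.0,
    min_similarity: float = 0.0,
    seed: int = 0,
) -> Dict[str, Dict]:
    """Density histograms of unique-pair Tanimoto similarities per
    comparison class (train-train, test-test, train-test).

    ``groups`` maps fold name -> item ids and must partition the table's
    ids.  ``sample_fraction`` subsamples items (seeded) before pairing;
    pairs below ``min_similarity`` are excluded from the histograms.
    """
    ids = sorted(items.ids)
    grouped = {k: sorted(v) for k, v in groups.items()}
    flat = sorted(i for v in grouped.values() for i in v)
    if flat != ids:
        raise InputError("groups must partition the feature-table ids")
    rng = np.random.default_rng(seed)
    sampled = {}
    for name, members in grouped.items():
        if not members:
            raise InputError(f"group {name!r} is empty")
        n_keep = max(1, int(round(sample_fraction * len(members))))
        sampled[name] = sorted(rng.choice(members, size=n_keep, replace=False))
    names = sorted(sampled)
    out: Dict[str, Dict] = {}
    edges = np.linspace(0.0, 1.0, bins + 1)
    for i, na in enumerate(names):
        for nb in names[i:]:
            if na == nb:
                mat = tanimoto_matrix(items.matrix(sampled[na]))
                iu = np.triu_indices(len(sampled[na]), k=1)
                sims = mat[iu]
            else:
                sims = tanimoto_matrix(
                    items.matrix(sampled[na]), items.matrix(sampled[nb])
                ).ravel()
            n_pairs = sims.size
            sims = sims[sims >= min_similarity]
            density, _ = (
                np.histogram(sims, bins=edges, density=True)
                if sims.size
                else (np.zeros(bins), edges)
            )
            out[f"{na}-{nb}"] = {
                "bin_edges": edges,
                "density": density,
                "n_pairs_total": int(n_pairs),
                "n_pairs_kept": int(sims.size),
            }
    return out


def embed_2d(
    features: FeatureTable, perplexity: float = 30.0, seed: int = 0
) -> Dict[str, np.ndarray]:
    """Seeded 2-D t-SNE coordinates per item (delegated to scikit-learn)."""
    n = len(features)
    if n < 3 * perplexity:
        raise InputError(
            f"need at least 3*perplexity={3 * perplexity:.0f} items, got {n}"
        )
    from sklearn.manifold import TSNE

    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(features.matrix())
    return dict(zip(features.ids, coords))
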