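"""Performance metrics for DTI prediction, including offset-corrected ones.

Besides the standard confusion-matrix scores (accuracy, precision, recall,
F1, MCC), RMSE and Spearman rank correlation, this module implements the
corrected variants used for regression models whose prediction distribution
is systematically shifted: the median-corrected RMSE/MCC (predictions are
translated so their median equals the true-value median before scoring) and
a 6-class MCC over fixed pChEMBL bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.stats

from dtibench.errors import InputError

#: 6-class pChEMBL bin edges; bins are half-open, lower-inclusive:
#: (-inf, 5.0), [5.0, 5.5), [5.5, 6.0), [6.0, 6.5), [6.5, 7.0), [7.0, inf)
CLASS_EDGES = (5.0, 5.5, 6.0, 6.5, 7.0)
N_CLASSES = 6


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class PredictionSet:
    """Paired true/predicted activity vectors."""

    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self):
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if self.y_true.shape != self.y_pred.shape or self.y_true.ndim != 1:
            raise InputError(
                f"y_true and y_pred must be 1-D and equal length, got "
                f"{self.y_true.shape} vs {self.y_pred.shape}"
            )

    @property
    def n(self) -> int:
        return self.y_true.shape[0]


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise InputError("label vectors differ in length")
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def classification_metrics(c: ConfusionCounts) -> Dict[str, float]:
    """Accuracy, precision, recall, F1 and MCC from confusion counts.

    Any score with a zero denominator is 0.0 by convention.
    """
    if c.n < 1:
        raise InputError("need at least one prediction")
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    accuracy = (tp + tn) / c.n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }


def rmse(p: PredictionSet) -> float:
    """Root mean squared error."""
    if p.n < 1:
        raise InputError("need at least one prediction")
    return float(np.sqrt(np.mean((p.y_true - p.y_pred) ** 2)))


def spearman(p: PredictionSet) -> float:
    """Spearman rank correlation (tie-safe: Pearson of average ranks)."""
    if p.n < 2:
        raise InputError("spearman needs at least 2 points")
    if np.all(p.y_true == p.y_true[0]) or np.all(p.y_pred == p.y_pred[0]):
        raise InputError("spearman undefined for a constant vector")
    return float(scipy.stats.spearmanr(p.y_true, p.y_pred).statistic)


def binarize(values: Sequence[float], cutoff: float) -> np.ndarray:
    """1 (active) iff value > cutoff, else 0 (boundary values inactive)."""
    arr = np.asarray(values, dtype=float)
    return (arr > cutoff).astype(int)


def median_shift(p: PredictionSet) -> PredictionSet:
    """Translate predictions so median(y_pred) == median(y_true).

    Rank-preserving, so Spearman is unchanged; removes a systematic offset
    before value-based scoring.
    """
    if p.n < 1:
        raise InputError("need at least one prediction")
    offset = float(np.median(p.y_true) - np.median(p.y_pred))
    return PredictionSet(p.y_true, p.y_pred + offset)


def median_corrected_rmse(p: PredictionSet) -> float:
    """RMSE after the median shift."""
    return rmse(median_shift(p))


def median_corrected_mcc(p: PredictionSet, cutoff: float) -> float:
    """MCC of the median-shifted predictions binarized at ``cutoff``."""
    shifted = median_shift(p)
    yt = binarize(shifted.y_true, cutoff)
    yp = binarize(shifted.y_pred, cutoff)
    return classification_metrics(confusion_counts(yt, yp))["mcc"]


def assign_activity_class(values: Sequence[float]) -> np.ndarray:
    """Map pChEMBL values to the 6 fixed activity classes (0-based)."""
    arr = np.asarray(values, dtype=float)
    return np.searchsorted(CLASS_EDGES, arr, side="right").astype(int)


def multiclass_mcc(p: PredictionSet, macro: bool = True) -> float:
    """6-bin multiclass MCC.

    With ``macro=True`` (default): unweighted mean of one-vs-rest binary
    MCCs over the 6 classes, degenerate classes contributing 0.0.  With
    ``macro=False``: the single multi-category (Gorodkin R_k) coefficient.
    """
    if p.n < 2:
        raise InputError("multiclass_mcc needs at least 2 points")
    ct = assign_activity_class(p.y_true)
    cp = assign_activity_class(p.y_pred)
    if macro:
        scores = []
        for k in range(N_CLASSES):
            c = confusion_counts((ct == k).astype(int), (cp == k).astype(int))
            scores.append(classification_metrics(c)["mcc"])
        return float(np.mean(scores))
    from sklearn.metrics import matthews_corrcoef

    return float(matthews_corrcoef(ct, cp))


def regression_report(
    p: PredictionSet, cutoff: Optional[float] = None
) -> Dict[str, float]:
    """Full regression-model score set.

    ``cutoff`` defaults to the median of y_true (the training-median rule
    should be applied by passing the training median explicitly).
    """
    if cutoff is None:
        cutoff = float(np.median(p.y_true))
    yt = binarize(p.y_true, cutoff)
    yp = binarize(p.y_pred, cutoff)
    cls = classification_metrics(confusion_counts(yt, yp))
    return {
        "rmse": rmse(p),
        "spearman": spearman(p),
        "median_corrected_rmse": median_corrected_rmse(p),
        "mcc": cls["mcc"],
        "f1": cls["f1"],
        "median_corrected_mcc": median_corrected_mcc(p, cutoff),
        "multiclass_mcc": multiclass_mcc(p),
        "cutoff": float(cutoff),
    }
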