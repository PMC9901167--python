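"""Metric implementations against independent brute-force oracles."""

import math

import numpy as np
import pytest

from dtibench import metrics
from dtibench.errors import InputError
from dtibench.metrics import ConfusionCounts, PredictionSet


# ---------------------------------------------------------------------------
# brute-force oracles: explicit loops over the definitions
# ---------------------------------------------------------------------------

def oracle_confusion(y_true, y_pred):
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def oracle_mcc(tp, tn, fp, fn):
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / denom if denom else 0.0


def oracle_rmse(y, yhat):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / len(y))


def oracle_rank(values):
    """Average ranks, 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(y, yhat):
    ry, rp = oracle_rank(list(y)), oracle_rank(list(yhat))
    my, mp = sum(ry) / len(ry), sum(rp) / len(rp)
    num = sum((a - my) * (b - mp) for a, b in zip(ry, rp))
    den = math.sqrt(sum((a - my) ** 2 for a in ry) * sum((b - mp) ** 2 for b in rp))
    return num / den


def oracle_class(value):
    if value < 5.0:
        return 0
    if value < 5.5:
        return 1
    if value < 6.0:
        return 2
    if value < 6.5:
        return 3
    if value < 7.0:
        return 4
    return 5


def oracle_multiclass_mcc(y, yhat):
    ct = [oracle_class(v) for v in y]
    cp = [oracle_class(v) for v in yhat]
    scores = []
    for k in range(6):
        tp, tn, fp, fn = oracle_confusion(
            [1 if c == k else 0 for c in ct], [1 if c == k else 0 for c in cp]
        )
        scores.append(oracle_mcc(tp, tn, fp, fn))
    return sum(scores) / 6


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

class TestClassificationMetrics:
    def test_hand_computed_mcc(self):
        rep = metrics.classification_metrics(ConfusionCounts(TP=2, TN=2, FP=1, FN=1))
        assert rep["mcc"] == pytest.approx(3 / 9)
        assert rep["accuracy"] == pytest.approx(4 / 6)

    def test_perfect_prediction(self):
        rep = metrics.classification_metrics(ConfusionCounts(TP=3, TN=4, FP=0, FN=0))
        assert rep["mcc"] == rep["f1"] == rep["accuracy"] == 1.0

    def test_degenerate_counts_zero_convention(self):
        rep = metrics.classification_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert rep["precision"] == rep["recall"] == rep["f1"] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            ConfusionCounts(TP=-1, TN=1, FP=0, FN=0)


class TestRegressionMetrics:
    def test_rmse_hand_example(self):
        assert metrics.rmse(PredictionSet([5, 6], [5, 8])) == pytest.approx(math.sqrt(2))

    def test_rmse_shift_by_constant(self):
        y = np.array([5.0, 6.0, 7.0])
        assert metrics.rmse(PredictionSet(y, y + 1.3)) == pytest.approx(1.3)

    def test_spearman_hand_example(self):
        # one adjacent swap: 1 - 6*2 / (4*15) = 0.8
        assert metrics.spearman(PredictionSet([1, 2, 3, 4], [1, 2, 4, 3])) == pytest.approx(0.8)

    def test_spearman_reversed(self):
        assert metrics.spearman(PredictionSet([1, 2, 3], [3, 2, 1])) == pytest.approx(-1.0)

    def test_spearman_constant_vector_rejected(self):
        with pytest.raises(InputError):
            metrics.spearman(PredictionSet([1, 2, 3], [5, 5, 5]))


class TestBinarize:
    def test_boundary_is_inactive(self):
        np.testing.assert_array_equal(
            metrics.binarize([7.0, 7.01, 6.99], cutoff=7.0), [0, 1, 0]
        )

    def test_empty_input(self):
        assert metrics.binarize([], cutoff=7.0).size == 0


class TestMedianCorrection:
    def test_pure_shift_gives_zero_rmse(self):
        p = metrics.median_shift(PredictionSet([5, 6, 7], [6, 7, 8]))
        np.testing.assert_allclose(p.y_pred, [5, 6, 7])
        assert metrics.rmse(p) == 0.0

    def test_aligned_predictions_unchanged(self):
        p = metrics.median_shift(PredictionSet([5, 6, 7], [5.5, 6.0, 6.5]))
        np.testing.assert_allclose(p.y_pred, [5.5, 6.0, 6.5])

    def test_median_equality_exact(self, rng):
        for _ in range(20):
            p = PredictionSet(rng.normal(6, 1, 31), rng.normal(8, 2, 31))
            shifted = metrics.median_shift(p)
            assert np.median(shifted.y_pred) == pytest.approx(np.median(p.y_true), abs=1e-12)

    def test_spearman_invariant_under_shift(self, rng):
        p = PredictionSet(rng.normal(6, 1, 40), rng.normal(9, 1, 40))
        assert metrics.spearman(metrics.median_shift(p)) == pytest.approx(
            metrics.spearman(p)
        )

    def test_offset_predictions_recover_mcc(self):
        # rank-perfect but offset by +3: plain binarization calls everything
        # active, corrected recovers the perfect separation
        y = np.array([5.0, 5.5, 6.5, 7.5, 8.0, 9.0])
        p = PredictionSet(y, y + 3.0)
        cutoff = 7.0
        plain = metrics.classification_metrics(
            metrics.confusion_counts(
                metrics.binarize(y, cutoff), metrics.binarize(p.y_pred, cutoff)
            )
        )["mcc"]
        corrected = metrics.median_corrected_mcc(p, cutoff)
        assert corrected == pytest.approx(1.0)
        assert corrected > plain

    def test_anticorrelated_corrected_mcc_nonpositive(self):
        y = np.array([5.0, 6.0, 8.0, 9.0])
        p = PredictionSet(y, np.array([9.0, 8.0, 6.0, 5.0]))
        assert metrics.median_corrected_mcc(p, cutoff=7.0) <= 0.0


class TestMulticlassMcc:
    def test_boundary_convention(self):
        assert metrics.assign_activity_class([5.5])[0] == 2
        assert metrics.assign_activity_class([5.4999])[0] == 1
        assert metrics.assign_activity_class([4.9])[0] == 0
        assert metrics.assign_activity_class([7.0])[0] == 5

    def test_perfect_binning_all_classes(self):
        y = np.array([4.5, 5.2, 5.7, 6.2, 6.7, 7.5, 4.8, 5.3, 5.8, 6.3, 6.8, 8.0])
        assert metrics.multiclass_mcc(PredictionSet(y, y.copy())) == pytest.approx(1.0)

    def test_hand_built_confusions(self, rng):
        y = rng.uniform(4, 8.5, 12)
        yhat = rng.uniform(4, 8.5, 12)
        p = PredictionSet(y, yhat)
        assert metrics.multiclass_mcc(p) == pytest.approx(
            oracle_multiclass_mcc(y, yhat), abs=1e-12
        )

    def test_order_invariance(self, rng):
        y = rng.uniform(4, 8.5, 50)
        yhat = rng.uniform(4, 8.5, 50)
        perm = rng.permutation(50)
        assert metrics.multiclass_mcc(PredictionSet(y, yhat)) == pytest.approx(
            metrics.multiclass_mcc(PredictionSet(y[perm], yhat[perm])), abs=1e-12
        )


def test_all_metrics_match_oracles_on_random_sets():
    """100 random prediction sets: every metric equals its brute-force oracle
    to 1e-9."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = int(rng.integers(5, 60))
        y = rng.uniform(3.5, 9.5, n)
        yhat = y + rng.normal(0, rng.uniform(0.1, 2.0), n) + rng.normal(0, 1)
        p = PredictionSet(y, yhat)
        cutoff = float(rng.uniform(5, 8))

        assert metrics.rmse(p) == pytest.approx(oracle_rmse(y, yhat), abs=1e-9)
        assert metrics.spearman(p) == pytest.approx(oracle_spearman(y, yhat), abs=1e-9)

        yt, yp = metrics.binarize(y, cutoff), metrics.binarize(yhat, cutoff)
        tp, tn, fp, fn = oracle_confusion(yt, yp)
        rep = metrics.classification_metrics(metrics.confusion_counts(yt, yp))
        assert rep["mcc"] == pytest.approx(oracle_mcc(tp, tn, fp, fn), abs=1e-9)
        n_tot = tp + tn + fp + fn
        assert rep["accuracy"] == pytest.approx((tp + tn) / n_tot, abs=1e-9)

        shifted = metrics.median_shift(p)
        offset = np.median(y) - np.median(yhat)
        assert metrics.median_corrected_rmse(p) == pytest.approx(
            oracle_rmse(y, yhat + offset), abs=1e-9
        )
        st, sp_ = metrics.binarize(shifted.y_true, cutoff), metrics.binarize(shifted.y_pred, cutoff)
        tp2, tn2, fp2, fn2 = oracle_confusion(st, sp_)
        assert metrics.median_corrected_mcc(p, cutoff) == pytest.approx(
            oracle_mcc(tp2, tn2, fp2, fn2), abs=1e-9
        )
        assert metrics.multiclass_mcc(p) == pytest.approx(
            oracle_multiclass_mcc(y, yhat), abs=1e-9
        )
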