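import numpy as np
import pytest

from dtibench import diagnostics
from dtibench.errors import ConsistencyError, DimensionError, InputError
from dtibench.io import FeatureTable
from dtibench.metrics import PredictionSet


def bit_table(rows, kind="compound"):
    return FeatureTable({k: np.asarray(v, dtype=float) for k, v in rows.items()}, kind=kind)


class TestKnnAd:
    def test_identical_items_give_one(self):
        fp = [1, 0, 1, 0, 1, 0, 1, 0]
        train = bit_table({f"t{i}": fp for i in range(6)})
        test = bit_table({"q": fp})
        assert diagnostics.knn_ad(test, train, k=5)["q"] == pytest.approx(1.0)

    def test_k_clamped_to_training_size(self):
        train = bit_table({"t1": [1, 1, 0, 0], "t2": [0, 0, 1, 1]})
        test = bit_table({"q": [1, 1, 0, 0]})
        # mean over the whole 2-item training set: (1.0 + 0.0) / 2
        assert diagnostics.knn_ad(test, train, k=5)["q"] == pytest.approx(0.5)

    def test_matches_sort_and_average_oracle(self, rng):
        train = bit_table(
            {f"t{i}": (rng.random(64) < 0.2).astype(float) for i in range(10)}
        )
        test = bit_table(
            {f"q{i}": (rng.random(64) < 0.2).astype(float) for i in range(4)}
        )
        from dtibench.compounds import tanimoto

        out = diagnostics.knn_ad(test, train, k=3)
        for q in test.ids:
            sims = sorted(
                (tanimoto(test[q], train[t]) for t in train.ids), reverse=True
            )
            assert out[q] == pytest.approx(np.mean(sims[:3]), abs=1e-12)

    def test_monotone_under_training_subset(self, rng):
        train = bit_table(
            {f"t{i}": (rng.random(64) < 0.2).astype(float) for i in range(12)}
        )
        sub = bit_table({k: train[k] for k in train.ids[:6]})
        test = bit_table({"q": (rng.random(64) < 0.2).astype(float)})
        assert diagnostics.knn_ad(test, sub, k=5)["q"] <= diagnostics.knn_ad(
            test, train, k=5
        )["q"] + 1e-12

    def test_empty_training_rejected(self):
        test = bit_table({"q": [1, 0]})
        with pytest.raises(InputError):
            diagnostics.knn_ad(test, bit_table({}, kind="compound"), k=5)


class TestPredictionAgreement:
    def test_identical_predictions(self):
        p = PredictionSet([6.0, 7.0], [6.1, 7.2])
        assert diagnostics.prediction_agreement(p, p) == 100.0

    def test_fully_disagreeing(self):
        a = PredictionSet([6.0, 7.0], [4.0, 5.2])
        b = PredictionSet([6.0, 7.0], [5.7, 6.2])
        assert diagnostics.prediction_agreement(a, b) == 0.0

    def test_symmetric(self, rng):
        a = PredictionSet(rng.uniform(4, 9, 30), rng.uniform(4, 9, 30))
        b = PredictionSet(a.y_true, rng.uniform(4, 9, 30))
        assert diagnostics.prediction_agreement(a, b) == diagnostics.prediction_agreement(b, a)


class TestAgreementMatrix:
    def test_identical_models(self):
        p = PredictionSet([6.0, 7.0, 5.0], [6.0, 7.0, 5.0])
        names, mat, order = diagnostics.agreement_matrix({"m1": p, "m2": p})
        np.testing.assert_allclose(mat, 100.0)

    def test_symmetry_and_diagonal(self, rng):
        preds = {
            f"m{i}": PredictionSet(rng.uniform(4, 9, 40), rng.uniform(4, 9, 40))
            for i in range(4)
        }
        _, mat, _ = diagnostics.agreement_matrix(preds)
        np.testing.assert_allclose(mat, mat.T)
        np.testing.assert_allclose(np.diag(mat), 100.0)
        assert (mat >= 0).all() and (mat <= 100).all()

    def test_block_structure_contiguous_in_leaf_order(self):
        y = np.linspace(4, 9, 24)
        block_a = y.copy()
        block_b = np.where(y > 6.5, 4.5, 8.5)
        preds = {
            "a1": PredictionSet(y, block_a),
            "a2": PredictionSet(y, block_a + 0.01),
            "b1": PredictionSet(y, block_b),
            "b2": PredictionSet(y, block_b + 0.01),
        }
        names, _, order = diagnostics.agreement_matrix(preds)
        ordered = [names[i][0] for i in order]
        assert ordered in (["a", "a", "b", "b"], ["b", "b", "a", "a"])

    def test_mismatched_universe_rejected(self):
        a = PredictionSet([6.0, 7.0], [6.0, 7.0])
        b = PredictionSet([6.0, 7.0, 8.0], [6.0, 7.0, 8.0])
        with pytest.raises(ConsistencyError):
            diagnostics.agreement_matrix({"a": a, "b": b})


class TestKsShift:
    def test_identical_folds_no_shift(self, rng):
        X = rng.normal(size=(50, 4))
        tr = FeatureTable({f"a{i}": X[i] for i in range(50)}, kind="protein")
        te = FeatureTable({f"b{i}": X[i] for i in range(50)}, kind="protein")
        rep = diagnostics.ks_shift(tr, te)
        np.testing.assert_allclose(rep.statistic, 0.0)
        assert rep.n_significant == 0

    def test_large_shift_detected(self, rng):
        A = rng.normal(size=(500, 3))
        B = rng.normal(size=(500, 3))
        B[:, 1] += 10.0
        tr = FeatureTable({f"a{i}": A[i] for i in range(500)}, kind="protein")
        te = FeatureTable({f"b{i}": B[i] for i in range(500)}, kind="protein")
        rep = diagnostics.ks_shift(tr, te, alpha=0.01)
        assert rep.p_value[1] < 0.01
        assert rep.statistic[1] > 0.9

    def test_ks_distance_matches_ecdf_oracle(self, rng):
        a = rng.normal(size=20)
        b = rng.normal(0.5, 1.2, size=20)
        tr = FeatureTable({f"a{i}": np.array([a[i]]) for i in range(20)}, kind="protein")
        te = FeatureTable({f"b{i}": np.array([b[i]]) for i in range(20)}, kind="protein")
        rep = diagnostics.ks_shift(tr, te)
        grid = np.concatenate([a, b])
        sup = max(
            abs((a <= x).mean() - (b <= x).mean()) for x in grid
        )
        assert rep.statistic[0] == pytest.approx(sup, abs=1e-12)

    def test_dimension_mismatch(self, rng):
        tr = FeatureTable({"a": np.zeros(3)}, kind="protein")
        te = FeatureTable({"b": np.zeros(4)}, kind="protein")
        with pytest.raises(DimensionError):
            diagnostics.ks_shift(tr, te)


class TestChi2Shift:
    def test_identical_bit_distributions(self, rng):
        X = (rng.random((100, 5)) < 0.3).astype(float)
        tr = FeatureTable({f"a{i}": X[i] for i in range(100)}, kind="compound")
        te = FeatureTable({f"b{i}": X[i] for i in range(100)}, kind="compound")
        assert diagnostics.chi2_shift(tr, te).n_significant == 0

    def test_extreme_association_detected(self):
        tr = FeatureTable({f"a{i}": np.array([0.0]) for i in range(200)}, kind="compound")
        te = FeatureTable({f"b{i}": np.array([1.0]) for i in range(200)}, kind="compound")
        rep = diagnostics.chi2_shift(tr, te, alpha=0.001)
        assert rep.n_significant == 1

    def test_chi2_value_matches_hand_formula(self):
        # 2x2 table [[30, 70], [50, 50]]: chi2 = sum (O-E)^2/E without correction
        tr = FeatureTable(
            {f"a{i}": np.array([1.0 if i < 30 else 0.0]) for i in range(100)},
            kind="compound",
        )
        te = FeatureTable(
            {f"b{i}": np.array([1.0 if i < 50 else 0.0]) for i in range(100)},
            kind="compound",
        )
        obs = np.array([[30, 70], [50, 50]], dtype=float)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        expected = row @ col / obs.sum()
        chi2 = ((obs - expected) ** 2 / expected).sum()
        rep = diagnostics.chi2_shift(tr, te)
        assert rep.statistic[0] == pytest.approx(chi2, abs=1e-9)

    def test_constant_bits_skipped(self):
        tr = FeatureTable({f"a{i}": np.array([0.0, 1.0]) for i in range(20)}, kind="compound")
        te = FeatureTable({f"b{i}": np.array([0.0, 1.0]) for i in range(20)}, kind="compound")
        rep = diagnostics.chi2_shift(tr, te)
        assert rep.skipped == [0, 1]
        assert rep.n_significant == 0


class TestPairwiseSimilarityHistogram:
    def test_identical_items_all_mass_at_one(self):
        items = bit_table({f"x{i}": [1, 0, 1, 0] for i in range(6)})
        groups = {"train": [f"x{i}" for i in range(4)], "test": ["x4", "x5"]}
        out = diagnostics.pairwise_similarity_histogram(items, groups)
        dens = out["train-train"]["density"]
        assert dens[-1] > 0 and dens[:-1].sum() == 0

    def test_pair_counts_partition(self, rng):
        items = bit_table(
            {f"x{i}": (rng.random(32) < 0.3).astype(float) for i in range(10)}
        )
        groups = {"train": [f"x{i}" for i in range(7)], "test": [f"x{i}" for i in range(7, 10)]}
        out = diagnostics.pairwise_similarity_histogram(items, groups)
        total = (
            out["test-train"]["n_pairs_total"]
            if "test-train" in out
            else out["train-test"]["n_pairs_total"]
        )
        assert (
            out["train-train"]["n_pairs_total"]
            + out["test-test"]["n_pairs_total"]
            + total
            == 45  # C(10,2)
        )

    def test_density_normalization(self, rng):
        items = bit_table(
            {f"x{i}": (rng.random(32) < 0.3).astype(float) for i in range(12)}
        )
        groups = {"train": [f"x{i}" for i in range(8)], "test": [f"x{i}" for i in range(8, 12)]}
        out = diagnostics.pairwise_similarity_histogram(items, groups, bins=10)
        for payload in out.values():
            if payload["n_pairs_kept"]:
                widths = np.diff(payload["bin_edges"])
                assert (payload["density"] * widths).sum() == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        items = bit_table({"x0": [1, 0]})
        with pytest.raises(InputError):
            diagnostics.pairwise_similarity_histogram(
                items, {"train": ["x0"], "test": []}
            )


class TestEmbed2d:
    def test_row_count_and_determinism(self, rng):
        X = np.vstack(
            [rng.normal(0, 1, size=(40, 6)), rng.normal(8, 1, size=(40, 6))]
        )
        ft = FeatureTable({f"x{i}": X[i] for i in range(80)}, kind="protein")
        a = diagnostics.embed_2d(ft, perplexity=10, seed=0)
        b = diagnostics.embed_2d(ft, perplexity=10, seed=0)
        assert len(a) == 80
        np.testing.assert_allclose(a["x0"], b["x0"])

    def test_separated_blobs_silhouette(self, rng):
        from sklearn.metrics import silhouette_score

        X = np.vstack(
            [rng.normal(0, 1, size=(50, 6)), rng.normal(12, 1, size=(50, 6))]
        )
        labels = np.array([0] * 50 + [1] * 50)
        ft = FeatureTable({f"x{i}": X[i] for i in range(100)}, kind="protein")
        coords = diagnostics.embed_2d(ft, perplexity=15, seed=1)
        emb = np.stack([coords[f"x{i}"] for i in range(100)])
        assert silhouette_score(emb, labels) > 0.5

    def test_too_few_items_rejected(self):
        ft = FeatureTable({f"x{i}": np.zeros(3) for i in range(5)}, kind="protein")
        with pytest.raises(InputError):
            diagnostics.embed_2d(ft, perplexity=30)
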