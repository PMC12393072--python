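"""ANOSIM, PCA, ripeness staging, LDA and confusion matrices."""

import numpy as np
import pandas as pd
import pytest

from durinose.errors import ValidationError
from durinose.multivariate import (
    LDAModel,
    anosim,
    assign_ripeness_stages,
    confusion,
    lda_fit,
    lda_predict,
    pairwise_distances,
    pca_fit,
)
from durinose.catalog import OUTDOOR_REFERENCE_AXES


class TestPairwiseDistances:
    def test_identical_rows_zero(self):
        D = pairwise_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert D[0, 1] == 0.0

    def test_three_four_five(self):
        D = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)

    def test_matches_naive_loop_oracle(self, rng):
        X = rng.normal(size=(20, 4))
        D = pairwise_distances(X)
        for i in range(20):
            for j in range(20):
                assert D[i, j] == pytest.approx(
                    np.sqrt(np.sum((X[i] - X[j]) ** 2)), abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_distances(np.array([[0.0, np.nan], [1.0, 2.0]]))


class TestAnosim:
    def test_full_separation_gives_r_one(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (8, 3)),
                       rng.normal(50, 0.5, (8, 3))])
        res = anosim(pairwise_distances(X), ["a"] * 8 + ["b"] * 8,
                     n_permutations=499, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_matches_reference_implementation(self, rng):
        import skbio
        X = np.vstack([rng.normal(0, 1, (12, 4)),
                       rng.normal(0.8, 1, (12, 4))])
        labels = ["a"] * 12 + ["b"] * 12
        D = pairwise_distances(X)
        res = anosim(D, labels, n_permutations=999, seed=3,
                     method="permutation")
        ref = skbio.stats.distance.anosim(skbio.DistanceMatrix(D),
                                          grouping=labels, permutations=999)
        assert res.R == pytest.approx(ref["test statistic"], abs=1e-12)
        # p-values are both Monte-Carlo; agree within joint precision
        assert res.p_value == pytest.approx(ref["p-value"], abs=0.05)

    def test_exact_p_matches_monte_carlo_on_3_plus_3(self, rng):
        X = rng.normal(size=(6, 4))
        labels = ["a"] * 3 + ["b"] * 3
        D = pairwise_distances(X)
        exact = anosim(D, labels, method="exact")
        assert exact.n_permutations == 20
        mc = anosim(D, labels, n_permutations=9999, seed=1,
                    method="permutation")
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 9999)
        assert abs(mc.p_value - exact.p_value) <= 2 * se + 1e-4

    def test_rank_based_r_invariant_under_monotone_transform(self, rng):
        X = rng.normal(size=(14, 4))
        labels = ["a"] * 7 + ["b"] * 7
        D = pairwise_distances(X)
        r1 = anosim(D, labels, n_permutations=99, seed=0).R
        r2 = anosim(D ** 2, labels, n_permutations=99, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_seeded_permutation_p_reproducible(self, rng):
        X = rng.normal(size=(18, 4))
        labels = ["a"] * 9 + ["b"] * 9
        D = pairwise_distances(X)
        p1 = anosim(D, labels, n_permutations=499, seed=7).p_value
        p2 = anosim(D, labels, n_permutations=499, seed=7).p_value
        assert p1 == p2

    def test_singleton_group_rejected(self, rng):
        D = pairwise_distances(rng.normal(size=(5, 2)))
        with pytest.raises(ValidationError):
            anosim(D, ["a", "a", "a", "a", "b"])

    def test_null_r_near_zero(self, rng):
        X = rng.normal(size=(30, 4))
        labels = ["a"] * 15 + ["b"] * 15
        res = anosim(pairwise_distances(X), labels, n_permutations=199,
                     seed=0)
        assert abs(res.R) < 0.1
        assert res.p_value > 0.05


class TestPca:
    def test_line_in_2d_explained_by_pc1(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 2 * t])
        res = pca_fit(X, scale=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_conservation(self, rng):
        X = rng.normal(size=(40, 5))
        res = pca_fit(X, scale=False)
        total = np.var(X, axis=0, ddof=1).sum()
        assert res.explained_variance.sum() == pytest.approx(total)

    def test_reconstruction_from_all_components(self, rng):
        X = rng.normal(size=(50, 4)) * [1, 10, 0.1, 3]
        res = pca_fit(X)
        assert np.allclose(res.reconstruct(), X, atol=1e-10)


class TestRipenessStaging:
    @staticmethod
    def _scores(day_centers, n=20, sd=0.2, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for day, c in day_centers.items():
            pts = rng.normal(c, sd, size=(n, 2))
            for p in pts:
                rows.append({"day": day, "PC1": p[0], "PC2": p[1]})
        return pd.DataFrame(rows)

    def test_identical_clouds_all_ripened(self):
        scores = self._scores({d: (0.0, 0.0) for d in range(1, 8)})
        stages = assign_ripeness_stages(scores, cracking_day=4)
        assert all(s.stage == "ripened" for s in stages)

    def test_widely_spaced_clouds_classic_pattern(self):
        scores = self._scores({d: (100.0 * d, 0.0) for d in range(1, 8)},
                              sd=0.1)
        stages = assign_ripeness_stages(scores, cracking_day=4)
        assert [s.stage for s in stages] == (
            ["before_ripening"] * 3 + ["ripened"] + ["after_ripening"] * 3)

    def test_sparse_day_unassigned(self):
        scores = self._scores({d: (0.0, 0.0) for d in range(1, 4)})
        scores = pd.concat([scores, pd.DataFrame(
            [{"day": 4, "PC1": 0.0, "PC2": 0.0},
             {"day": 4, "PC1": 0.1, "PC2": 0.1}])], ignore_index=True)
        stages = assign_ripeness_stages(scores, cracking_day=2)
        by_day = {s.day: s.stage for s in stages}
        assert by_day[4] == "unassigned"

    def test_missing_cracking_day_rejected(self):
        scores = self._scores({1: (0, 0), 2: (1, 1)})
        with pytest.raises(ValidationError):
            assign_ripeness_stages(scores, cracking_day=5)


class TestLda:
    def test_two_class_axis_parallel_to_fisher_direction(self, rng):
        for _ in range(30):
            mu = rng.normal(size=4) * 2
            X = np.vstack([rng.normal(0, 1, (25, 4)),
                           rng.normal(mu, 1, (25, 4))])
            y = np.array(["a"] * 25 + ["b"] * 25)
            model = lda_fit(X, y)
            assert model.n_axes == 1
            mu_a, mu_b = X[y == "a"].mean(0), X[y == "b"].mean(0)
            da = X[y == "a"] - mu_a
            db = X[y == "b"] - mu_b
            Sw = (da.T @ da + db.T @ db) / (50 - 2)
            w = np.linalg.solve(Sw, mu_a - mu_b)
            cos = abs(w @ model.coefficients[:, 0]) / (
                np.linalg.norm(w) * np.linalg.norm(model.coefficients[:, 0]))
            assert cos > 0.999

    def test_three_separated_gaussians_train_accuracy_100(self, rng):
        X = np.vstack([rng.normal((0, 0, 0), 0.2, (20, 3)),
                       rng.normal((10, 0, 0), 0.2, (20, 3)),
                       rng.normal((0, 10, 0), 0.2, (20, 3))])
        y = np.repeat(["a", "b", "c"], 20)
        model = lda_fit(X, y)
        assert model.n_axes == 2
        assert (lda_predict(model, X) == y).all()

    def test_channel_rescaling_leaves_predictions_invariant(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 4)),
                       rng.normal(1.0, 1, (30, 4))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        scale = np.array([3.0, 0.1, 1.0, 42.0])
        pred1 = lda_predict(lda_fit(X, y), X)
        pred2 = lda_predict(lda_fit(X * scale, y), X * scale)
        assert (pred1 == pred2).all()

    def test_agrees_with_sklearn_predictions(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        X = np.vstack([rng.normal(0, 1, (40, 4)),
                       rng.normal(0.9, 1, (40, 4)),
                       rng.normal((0, 2, 0, 0), 1, (40, 4))])
        y = np.repeat(["a", "b", "c"], 40)
        ours = lda_predict(lda_fit(X, y), X)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert (ours == ref).mean() > 0.95

    def test_stored_reference_axes_project_unit_basis_vector(self):
        model = LDAModel.from_coefficients(OUTDOOR_REFERENCE_AXES)
        unit = pd.DataFrame([{ "GM102B": 0.0, "GM302B": 1.0,
                               "GM502B": 0.0, "GM702B": 0.0 }])
        z = model.project(unit)
        assert z[0, 0] == pytest.approx(0.23079)
        assert z[0, 1] == pytest.approx(0.0058381)

    def test_canonical_sign_largest_coefficient_positive(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 4)),
                       rng.normal(1.5, 1, (30, 4))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        model = lda_fit(X, y)
        for j in range(model.n_axes):
            lead = np.argmax(np.abs(model.coefficients[:, j]))
            assert model.coefficients[lead, j] > 0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            lda_fit(rng.normal(size=(10, 3)), ["a"] * 10)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        y = ["a", "b", "c", "a", "b"]
        cm = confusion(y, y)
        assert np.trace(cm.counts) == 5
        assert all(v == 100.0 for v in cm.per_class_accuracy().values())

    def test_conserves_sample_count(self, rng):
        true = rng.choice(["a", "b", "c"], size=200)
        pred = rng.choice(["a", "b", "c"], size=200)
        assert confusion(true, pred).n == 200

    def test_class_absent_from_truth_has_zero_column(self):
        cm = confusion(["b", "b"], ["b", "c"], classes=["a", "b", "c"])
        frame = cm.to_frame()
        assert frame["a"].sum() == 0
        assert np.isnan(cm.per_class_accuracy()["a"])

    def test_reference_outdoor_counts_give_reported_accuracies(self):
        """Readings distributed as in the original outdoor test set (150
        fruit readings per durian class, none of outdoor air) yield the
        reported 61.3% / 60.7% per-class accuracies."""
        true = ["durian"] * 150 + ["durian_mealybug"] * 150
        pred = (["durian"] * 92 + ["durian_mealybug"] * 58
                + ["durian"] * 59 + ["durian_mealybug"] * 91)
        cm = confusion(true, pred, classes=["air", "durian",
                                            "durian_mealybug"])
        acc = cm.per_class_accuracy()
        assert acc["durian"] == pytest.approx(61.3, abs=0.05)
        assert acc["durian_mealybug"] == pytest.approx(60.7, abs=0.05)
        assert cm.counts[0].sum() == 0  # air row empty
        assert cm.n == 300
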