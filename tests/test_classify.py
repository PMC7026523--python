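"""Classifier stack: PCA transform, linear SVM with decision-value scoring,
Platt calibration, AdaBoost and bagged-tree ensembles, CV and PC selection.

Oracles are kept independent of the implementation path: the SVM is checked
against a primal quadratic-program solve, Platt scaling against a likelihood
grid search, the repeated-measures ANOVA against statsmodels, and the
single-stump AdaBoost against exhaustive threshold enumeration.
"""

import numpy as np
import pandas as pd
import pytest
from _oracles import best_stump_oracle, platt_grid_oracle, svm_primal_oracle

from emscore import classify
from emscore.classify import EPITHELIAL, MESENCHYMAL
from emscore.exceptions import SchemaError


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def _toy_table(n_a=332, n_b=309, seed=0):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["f1", "f2", "f3"])
    df["line"] = ["GIE"] * n_a + ["HGF"] * n_b
    return df


class TestPartition:
    def test_default_yields_481_training_cells(self):
        train, test = classify.partition_data(_toy_table(), test_n=80, seed=3)
        assert len(train) == 481
        assert (train["line"] == "GIE").sum() == 252
        assert (train["line"] == "HGF").sum() == 229
        assert len(test) == 160

    def test_deterministic(self):
        t1 = classify.partition_data(_toy_table(), seed=5)[0]
        t2 = classify.partition_data(_toy_table(), seed=5)[0]
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_holdout(self):
        train, test = classify.partition_data(_toy_table(), test_n=0, seed=0)
        assert len(train) == 641 and len(test) == 0

    def test_insufficient_cells(self):
        with pytest.raises(ValueError):
            classify.partition_data(_toy_table(50, 50), test_n=80)


class TestPCA:
    def test_training_scores_centered(self, rng):
        x = rng.normal(size=(40, 17)) * rng.uniform(0.5, 20, 17)
        model = classify.pca_fit(x, k=6)
        scores = classify.pca_transform(model, x)
        assert np.abs(scores.mean(axis=0)).max() < 1e-10

    def test_explained_variance_nonincreasing(self, rng):
        x = rng.normal(size=(60, 17))
        model = classify.pca_fit(x, k=17)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_2d_principal_axis_matches_analytic(self, rng):
        """PC1 of standardized correlated Gaussians is the (1,1)/√2 axis."""
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=4000)
        model = classify.pca_fit(x, k=2)
        v = model.loadings[0] / np.linalg.norm(model.loadings[0])
        analytic = np.array([1.0, 1.0]) / np.sqrt(2)
        angle = np.degrees(np.arccos(np.clip(abs(v @ analytic), 0, 1)))
        assert angle < 1.0

    def test_constant_feature_guard(self, rng):
        x = rng.normal(size=(30, 4))
        x[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            model = classify.pca_fit(x, k=2)
        assert model.scales[2] == 1.0

    def test_schema_mismatch(self, rng):
        x = rng.normal(size=(30, 4))
        model = classify.pca_fit(x, k=2)
        df = pd.DataFrame(x, columns=["a", "b", "c", "d"])
        with pytest.raises(SchemaError):
            classify.pca_transform(model, df)


class TestLinearSVM:
    def test_analytic_max_margin_1d(self):
        x = np.array([[-1.0], [1.0]])
        y = np.array([EPITHELIAL, MESENCHYMAL])
        model = classify.train_linear_svm(x, y, C=1.0)
        assert model.beta[0] == pytest.approx(1.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)

    def test_label_swap_negates(self, rng):
        x = rng.normal(size=(20, 2)) + np.array([[2.0, 0]]) * rng.choice([1, -1], 20)[:, None]
        y = np.where(x[:, 0] > 0, MESENCHYMAL, EPITHELIAL)
        m1 = classify.train_linear_svm(x, y)
        m2 = classify.train_linear_svm(x, -y)
        np.testing.assert_allclose(m1.beta, -m2.beta, atol=1e-6)
        assert m1.b == pytest.approx(-m2.b, abs=1e-6)

    def test_duplication_invariance(self, rng):
        x = rng.normal(size=(12, 2)) + np.array([[3.0, 0]]) * rng.choice([1, -1], 12)[:, None]
        y = np.where(x[:, 0] > 0, 1, -1)
        m1 = classify.train_linear_svm(x, y)
        m2 = classify.train_linear_svm(np.vstack([x, x]), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-5)
        assert m1.b == pytest.approx(m2.b, abs=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify.train_linear_svm(np.zeros((5, 2)), np.ones(5, dtype=int))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_qp_oracle_equivalence(self, seed):
        """β, b agree with a primal QP solve on ≤10-point toy sets."""
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 11)
        x = rng.normal(size=(n, 2))
        y = np.where(x[:, 0] + 0.3 * rng.normal(size=n) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        model = classify.train_linear_svm(x, y, C=1.0)
        w_ref, b_ref = svm_primal_oracle(x, y, C=1.0)
        np.testing.assert_allclose(model.beta, w_ref, atol=1e-4)
        assert model.b == pytest.approx(b_ref, abs=1e-4)


class TestSVMScore:
    def test_hyperplane_point_scores_zero(self):
        model = classify.LinearSVMModel(beta=np.array([2.0, -1.0]), b=0.5)
        x = np.array([0.0, 0.5])  # 2*0 - 1*0.5 + 0.5 = 0
        assert classify.svm_score(model, x) == pytest.approx(0.0)

    def test_plain_projection(self):
        model = classify.LinearSVMModel(beta=np.array([1.0, 0.0]), b=0.0)
        assert classify.svm_score(model, np.array([2.0, 0.0])) == pytest.approx(2.0)

    def test_kernel_scale_divides(self):
        m1 = classify.LinearSVMModel(beta=np.array([1.0]), b=0.0, kernel_scale=1.0)
        m2 = classify.LinearSVMModel(beta=np.array([1.0]), b=0.0, kernel_scale=2.0)
        x = np.array([3.0])
        assert classify.svm_score(m2, x) == pytest.approx(classify.svm_score(m1, x) / 2)

    def test_dimension_mismatch(self):
        model = classify.LinearSVMModel(beta=np.array([1.0, 2.0]), b=0.0)
        with pytest.raises(ValueError):
            classify.svm_score(model, np.array([1.0, 2.0, 3.0]))

    def test_sign_equals_predicted_class(self, rng):
        model = classify.LinearSVMModel(beta=rng.normal(size=3), b=0.2)
        x = rng.normal(size=(50, 3))
        s = classify.svm_score(model, x)
        pred = classify.svm_predict(model, x)
        assert np.all((s > 0) == (pred == MESENCHYMAL))


class TestPlatt:
    def test_sigmoid_midpoint(self):
        model = classify.PlattModel(A=-1.0, B=0.0)
        assert classify.platt_posterior(model, 0.0) == pytest.approx(0.5)

    def test_symmetric_scores_give_zero_intercept(self):
        s = np.array([-3, -2, -1, -0.5, 0.5, 1, 2, 3], dtype=float)
        y = np.where(s > 0, MESENCHYMAL, EPITHELIAL)
        model = classify.platt_fit(s, y)
        assert abs(model.B) < 1e-3
        assert model.A < 0  # higher score => higher mesenchymal probability

    def test_monotone_posterior(self, rng):
        s = rng.normal(size=60) + np.where(rng.random(60) > 0.5, 1.5, -1.5)
        y = np.where(s > 0, 1, -1)
        model = classify.platt_fit(s, y)
        grid = np.linspace(-5, 5, 200)
        p = classify.platt_posterior(model, grid)
        assert np.all(np.diff(p) > 0)

    def test_grid_search_oracle(self, rng):
        s = np.concatenate([rng.normal(-1.2, 0.6, 10), rng.normal(1.2, 0.6, 10)])
        y = np.array([EPITHELIAL] * 10 + [MESENCHYMAL] * 10)
        model = classify.platt_fit(s, y)
        a_grid = np.arange(model.A - 0.05, model.A + 0.05, 1e-3)
        b_grid = np.arange(model.B - 0.05, model.B + 0.05, 1e-3)
        a_ref, b_ref = platt_grid_oracle(s, y, a_grid, b_grid)
        assert model.A == pytest.approx(a_ref, abs=1e-3)
        assert model.B == pytest.approx(b_ref, abs=1e-3)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            classify.platt_fit(np.ones(10), np.array([1, -1] * 5))


class TestBoost:
    def test_alpha_closed_form(self, rng):
        x = rng.normal(size=(40, 2))
        y = np.where(x[:, 0] + 0.5 * rng.normal(size=40) > 0, 1, -1)
        model = classify.train_boost(x, y, T=20, seed=0)
        expected = 0.5 * np.log((1 - model.errors) / model.errors)
        np.testing.assert_allclose(model.alphas, expected, rtol=1e-12)
        assert np.all(model.errors > 0) and np.all(model.errors < 0.5)

    def test_alpha_values(self):
        # ε = 0.1 → a = ½·ln 9; ε = 0.5 → a = 0 by the closed form
        assert 0.5 * np.log((1 - 0.1) / 0.1) == pytest.approx(1.0986, abs=1e-4)
        assert 0.5 * np.log((1 - 0.5) / 0.5) == 0.0

    def test_single_stump_matches_bruteforce(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0], [6.0], [7.0]])
        y = np.array([-1, -1, -1, 1, -1, 1, 1, 1])
        model = classify.train_boost(x, y, T=1, max_depth=1, seed=0)
        w = np.full(8, 1 / 8)
        err_ref, (j, c, sign) = best_stump_oracle(x, y, w)
        assert model.errors[0] == pytest.approx(err_ref, abs=1e-12)
        a1 = 0.5 * np.log((1 - err_ref) / err_ref)
        pred_ref = np.where(x[:, j] <= c, -sign, sign)
        f = classify.boost_score(model, x)
        np.testing.assert_allclose(f, model.learning_rate * a1 * pred_ref, atol=1e-12)

    def test_score_sign_is_prediction(self, rng):
        x = rng.normal(size=(60, 2))
        y = np.where(x[:, 0] > 0, 1, -1)
        model = classify.train_boost(x, y, T=10, seed=1)
        f = classify.boost_score(model, x)
        assert np.all(np.sign(f) == y)  # separable by the first feature


class TestBag:
    def test_weighted_posterior_arithmetic(self):
        # two learners, weights (1, 3), posteriors (0.2, 0.6) → 0.5
        leaf = lambda p: classify._TreePredictor.from_dict({
            "children_left": [-1], "children_right": [-1], "feature": [-2],
            "threshold": [-2.0], "proba": [[1 - p, p]],
        })
        model = classify.BagModel(
            learners=[leaf(0.2), leaf(0.6)], weights=np.array([1.0, 3.0]),
            included=np.array([True, True]), T=2,
        )
        x = np.zeros((1, 3))
        assert classify.bag_posterior(model, x)[0] == pytest.approx(0.5)

    def test_unanimous_learners(self):
        leaf = classify._TreePredictor.from_dict({
            "children_left": [-1], "children_right": [-1], "feature": [-2],
            "threshold": [-2.0], "proba": [[0.0, 1.0]],
        })
        model = classify.BagModel(learners=[leaf] * 4, weights=np.ones(4),
                                  included=np.ones(4, bool), T=4)
        assert classify.bag_posterior(model, np.zeros((1, 2)))[0] == pytest.approx(1.0)

    def test_posteriors_sum_to_one(self, rng):
        x = rng.normal(size=(50, 3))
        y = np.where(x[:, 0] > 0, 1, -1)
        model = classify.train_bag(x, y, T=15, seed=2)
        xq = rng.normal(size=(10, 3))
        pm = classify.bag_posterior(model, xq, MESENCHYMAL)
        pe = classify.bag_posterior(model, xq, EPITHELIAL)
        np.testing.assert_allclose(pm + pe, 1.0, atol=1e-12)

    def test_empty_inclusion_rejected(self):
        leaf = classify._TreePredictor.from_dict({
            "children_left": [-1], "children_right": [-1], "feature": [-2],
            "threshold": [-2.0], "proba": [[0.5, 0.5]],
        })
        model = classify.BagModel(learners=[leaf], weights=np.ones(1),
                                  included=np.zeros(1, bool), T=1)
        with pytest.raises(ValueError):
            classify.bag_posterior(model, np.zeros((1, 2)))


class TestCrossValidation:
    def test_separable_data_perfect(self, rng):
        x = np.vstack([rng.normal(-4, 0.3, (30, 2)), rng.normal(4, 0.3, (30, 2))])
        y = np.array([-1] * 30 + [1] * 30)
        cv = classify.crossvalidate(classify.svm_trainer(), x, y, seed=0)
        assert np.all(cv.accuracies == 1.0)

    def test_permutation_null(self, rng):
        x = rng.normal(size=(120, 3))
        y = np.array([-1, 1] * 60)  # labels independent of features
        cv = classify.crossvalidate(classify.svm_trainer(), x, y,
                                    folds=5, repeats=3, seed=0)
        assert abs(cv.mean - 0.5) < 0.15

    def test_deterministic(self, rng):
        x = rng.normal(size=(40, 2))
        y = np.where(x[:, 0] > 0, 1, -1)
        c1 = classify.crossvalidate(classify.svm_trainer(), x, y, seed=9)
        c2 = classify.crossvalidate(classify.svm_trainer(), x, y, seed=9)
        np.testing.assert_array_equal(c1.accuracies, c2.accuracies)


class TestRMAnova:
    def test_identical_accuracies(self):
        f, p = classify.rm_anova(np.full((5, 4), 0.9))
        assert f == 0.0 and p == 1.0

    def test_hand_sums_of_squares(self):
        """F on a 4-repeat × 3-condition table matches statsmodels AnovaRM."""
        table = np.array([
            [0.90, 0.94, 0.95],
            [0.88, 0.93, 0.96],
            [0.91, 0.95, 0.94],
            [0.89, 0.92, 0.97],
        ])
        f, p = classify.rm_anova(table)
        from statsmodels.stats.anova import AnovaRM

        long = pd.DataFrame({
            "subject": np.repeat(np.arange(4), 3),
            "cond": np.tile(np.arange(3), 4),
            "acc": table.ravel(),
        })
        res = AnovaRM(long, "acc", "subject", within=["cond"]).fit()
        f_ref = float(res.anova_table["F Value"].iloc[0])
        p_ref = float(res.anova_table["Pr > F"].iloc[0])
        assert f == pytest.approx(f_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestPCSelection:
    def test_selects_informative_count(self, rng):
        """The class signal sits in one feature while the dominant variance
        axis is pure correlated noise, so the 1-PC model is near chance and
        adding components helps: the ANOVA flags the difference and k* > 1."""
        n = 200
        y = np.array([-1, 1] * (n // 2))
        shared = rng.normal(size=n)
        x = np.column_stack([
            0.8 * y + 0.7 * rng.normal(size=n),   # the informative axis
            shared + 0.2 * rng.normal(size=n),    # correlated noise pair:
            shared + 0.2 * rng.normal(size=n),    #   dominates PC1
            0.5 * rng.normal(size=n),
            0.5 * rng.normal(size=n),
        ])
        k_star, report = classify.select_pc_count(
            x, y, candidates=(1, 2, 3), folds=4, repeats=3, seed=0)
        assert report.acc_table.shape == (3, 3)
        assert report.acc_table[:, 0].mean() < 0.65  # 1 PC ≈ chance
        assert report.p_value < 0.05
        assert k_star >= 2

    def test_requires_multiple_candidates(self, rng):
        with pytest.raises(ValueError):
            classify.select_pc_count(rng.normal(size=(20, 3)),
                                     np.array([-1, 1] * 10), candidates=(2,))


class TestBundle:
    def test_json_round_trip(self, tmp_path, rng):
        df = pd.DataFrame(rng.normal(size=(60, 17)),
                          columns=classify.FEATURE_NAMES if hasattr(classify, "FEATURE_NAMES")
                          else None)
        from emscore.features import FEATURE_NAMES
        df.columns = FEATURE_NAMES
        df["line"] = ["GIE", "HGF"] * 30
        df.loc[df["line"] == "HGF", FEATURE_NAMES[:4]] += 2.0
        model = classify.train_em_model(df, k=4, T=10, seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = classify.EMModel.from_json(path)
        s1 = classify.transfer_score(model, df)
        s2 = classify.transfer_score(loaded, df)
        for col in ["svm_score", "platt_posterior", "boost_score", "bag_posterior"]:
            np.testing.assert_allclose(s1[col], s2[col], atol=1e-12)

    def test_epithelial_centroid_scores_negative(self, archetype_split, trained_model):
        train, _ = archetype_split
        centroid = train[train["line"] == "GIE"].mean(numeric_only=True)
        row = pd.DataFrame([centroid])[list(trained_model.pca.feature_names)]
        x = classify.pca_transform(trained_model.pca, row)
        assert classify.svm_score(trained_model.svm, x)[0] < 0
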