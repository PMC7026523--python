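"""Evaluation statistics: ROC/AUC, outlier rule, correlations, order
statistics and model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import auc_pair_counting

from emscore import evaluate


class TestRocAuc:
    def test_perfect_separation(self):
        s = np.array([-2, -1.5, -1, 1, 1.5, 2], dtype=float)
        y = np.array([-1, -1, -1, 1, 1, 1])
        _, auc = evaluate.roc_auc(s, y)
        assert auc == 1.0

    def test_constant_scores(self):
        s = np.ones(10)
        y = np.array([-1, 1] * 5)
        _, auc = evaluate.roc_auc(s, y)
        assert auc == pytest.approx(0.5)

    def test_six_point_oracle(self):
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        y = np.array([-1, -1, 1, -1, 1, 1])
        _, auc = evaluate.roc_auc(s, y)
        assert auc == pytest.approx(auc_pair_counting(s, y), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(6, 50))
    def test_pair_counting_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        s = np.round(rng.normal(size=n), 1)  # coarse values force ties
        y = rng.choice([-1, 1], size=n)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        _, auc = evaluate.roc_auc(s, y)
        assert auc == pytest.approx(auc_pair_counting(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate.roc_auc(np.arange(5.0), np.ones(5))


class TestOutliers:
    def test_planted_extreme_value(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 99), [10.0]])
        sd = scores.std(ddof=1)
        assert abs(10.0 - scores.mean()) / sd > 5.6  # construction is valid
        retained, excluded = evaluate.exclude_outliers(scores, sd_threshold=5.6)
        assert excluded == [99]
        assert len(retained) == 99

    def test_infinite_threshold(self, rng):
        scores = rng.normal(size=50)
        retained, excluded = evaluate.exclude_outliers(scores, sd_threshold=np.inf)
        assert excluded == [] and len(retained) == 50

    def test_zero_sd_no_exclusions(self):
        retained, excluded = evaluate.exclude_outliers(np.full(10, 3.0))
        assert excluded == [] and len(retained) == 10

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            evaluate.exclude_outliers([1.0, 2.0])


class TestCorrelations:
    def test_self_correlation(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20)})
        rep = evaluate.score_correlations(df, columns=["a"])
        row = rep.iloc[0]
        assert row["pearson"] == pytest.approx(1.0)
        assert row["spearman"] == pytest.approx(1.0)

    def test_monotone_transform(self, rng):
        s = rng.normal(size=100)
        df = pd.DataFrame({"s": s, "sig": 1 / (1 + np.exp(-4 * s))})
        rep = evaluate.score_correlations(df, columns=["s", "sig"])
        row = rep[(rep.score_a == "s") & (rep.score_b == "sig")].iloc[0]
        assert row["spearman"] == pytest.approx(1.0, abs=1e-12)
        assert row["pearson"] < 1.0

    def test_manual_rank_oracle(self):
        a = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        b = np.array([2.0, 8.0, 1.0, 7.0, 0.5, 0.1, 6.0])
        df = pd.DataFrame({"a": a, "b": b})
        rep = evaluate.score_correlations(df, columns=["a", "b"])
        row = rep[(rep.score_a == "a") & (rep.score_b == "b")].iloc[0]
        ra = pd.Series(a).rank().to_numpy()
        rb = pd.Series(b).rank().to_numpy()
        manual = np.corrcoef(ra, rb)[0, 1]
        assert row["spearman"] == pytest.approx(manual, abs=1e-12)

    def test_constant_column_reported_nan(self):
        df = pd.DataFrame({"a": np.arange(5.0), "b": np.ones(5)})
        rep = evaluate.score_correlations(df, columns=["a", "b"])
        row = rep[(rep.score_a == "a") & (rep.score_b == "b")].iloc[0]
        assert np.isnan(row["pearson"]) and np.isnan(row["spearman"])


class TestRepresentatives:
    def _frame(self, scores):
        return pd.DataFrame({"svm_score": scores,
                             "cell_id": np.arange(1, len(scores) + 1)})

    def test_five_distinct_scores(self):
        rep = evaluate.representative_cells(self._frame([1, 2, 3, 4, 5]))
        assert rep["score"].tolist() == [1, 2, 3, 4, 5]
        assert rep["statistic"].tolist() == ["min", "q1", "median", "q3", "max"]

    def test_tie_goes_to_lower_id(self):
        rep = evaluate.representative_cells(self._frame([1, 3, 3, 3, 5]))
        med = rep[rep.statistic == "median"].iloc[0]
        assert med["cell_id"] == 2  # first of the tied median scores

    def test_sort_oracle(self, rng):
        scores = rng.normal(size=101)
        rep = evaluate.representative_cells(self._frame(scores))
        for _, row in rep.iterrows():
            q = {"min": 0, "q1": 0.25, "median": 0.5, "q3": 0.75, "max": 1.0}[
                row["statistic"]]
            target = np.quantile(scores, q)  # linear interpolation
            best = np.abs(scores - target).min()
            assert abs(row["score"] - target) == pytest.approx(best, abs=1e-12)

    def test_partial_below_five(self):
        rep = evaluate.representative_cells(self._frame([2.0, 1.0, 3.0]))
        assert len(rep) == 3 and rep["partial"].all()


class TestCompareModels:
    def test_identical_vectors(self):
        t, p = evaluate.compare_models([0.9, 0.91, 0.92], [0.9, 0.91, 0.92])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_formula(self):
        a = np.array([0.90, 0.92, 0.94])
        b = np.array([0.85, 0.88, 0.86])
        t, p = evaluate.compare_models(a, b)
        sp = np.sqrt(((a.var(ddof=1) + b.var(ddof=1)) / 2) * (2 / 3))
        t_ref = (a.mean() - b.mean()) / sp
        assert t == pytest.approx(t_ref, abs=1e-10)

    def test_swap_negates_t(self, rng):
        a, b = rng.normal(0.9, 0.01, 5), rng.normal(0.88, 0.01, 5)
        t1, p1 = evaluate.compare_models(a, b)
        t2, p2 = evaluate.compare_models(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            evaluate.compare_models([0.9], [0.8])


class TestConfusion:
    def test_accuracy_equals_mean_correctness(self, rng):
        pred = rng.choice(["E", "M"], 40)
        truth = rng.choice(["E", "M"], 40)
        mat = evaluate.confusion_matrix(pred, truth)
        assert mat.to_numpy().sum() == 40
        acc = evaluate.accuracy_from_confusion(mat)
        assert acc == pytest.approx(np.mean(pred == truth))

    def test_histogram_counts_reconcile(self, rng):
        scores = rng.normal(size=200)
        edges = evaluate.pooled_histogram_bins(scores)
        counts, _ = np.histogram(scores, bins=edges)
        assert counts.sum() == 200
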