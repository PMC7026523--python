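"""Evaluation and reporting: ROC/AUC, confusion tables, outlier exclusion,
score-score correlations, histograms and representative-cell selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classify import MESENCHYMAL


# ---------------------------------------------------------------------------
# ROC / confusion
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, positive=MESENCHYMAL):
    """ROC points and trapezoid AUC for a score sweep.

    The AUC equals the Mann-Whitney U statistic divided by n₁·n₂ (the
    probability a random positive outscores a random negative, ties half).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == positive
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(pos.astype(int), scores)
    return np.column_stack([fpr, tpr]), float(_sk_auc(fpr, tpr))


def confusion_matrix(predicted, truth, classes=("E", "M")) -> pd.DataFrame:
    """2×2 confusion table (rows: truth, columns: prediction)."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(truth, predicted):
        mat.loc[t, p] += 1
    return mat


def accuracy_from_confusion(mat: pd.DataFrame) -> float:
    total = mat.to_numpy().sum()
    return float(np.trace(mat.to_numpy()) / total) if total else float("nan")


# ---------------------------------------------------------------------------
# outliers, correlations, order statistics
# ---------------------------------------------------------------------------

def exclude_outliers(scores, sd_threshold: float = 5.6):
    """Single-pass exclusion of scores > ``sd_threshold`` SDs from the mean.

    Mean and SD are computed once on the full population; if the SD is zero
    nothing is excluded. Returns (retained indices, excluded indices).
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 scores")
    sd = s.std(ddof=1)
    if sd == 0:
        return list(s.index), []
    dev = (s - s.mean()).abs() / sd
    excluded = list(s.index[dev > sd_threshold])
    retained = list(s.index[dev <= sd_threshold])
    return retained, excluded


def score_correlations(score_table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson and Spearman correlations for every pair of score columns.

    A constant column makes the correlation undefined; it is reported as
    NaN rather than raising.
    """
    cols = columns or [c for c in score_table.columns
                       if score_table[c].dtype.kind == "f"]
    if len(score_table) < 3:
        raise ValueError("need at least 3 cells")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            xa = score_table[a].to_numpy(dtype=float)
            xb = score_table[b].to_numpy(dtype=float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                pear = spear = float("nan")
            else:
                pear = float(stats.pearsonr(xa, xb).statistic)
                spear = float(stats.spearmanr(xa, xb).statistic)
            rows.append({"score_a": a, "score_b": b,
                         "pearson": pear, "spearman": spear})
    return pd.DataFrame(rows)


def representative_cells(score_set: pd.DataFrame, score_col: str = "svm_score",
                         id_col: str = "cell_id") -> pd.DataFrame:
    """Cells nearest the min, Q1, median, Q3 and max of a score distribution.

    Quartiles use linear interpolation; ties on distance resolve to the
    lower cell id. With fewer than five cells the available order statistics
    are returned with a ``partial`` flag.
    """
    df = score_set.reset_index(drop=True)
    scores = df[score_col].to_numpy(dtype=float)
    n = len(df)
    if n == 0:
        raise ValueError("empty score set")
    stats_wanted = [("min", 0.0), ("q1", 0.25), ("median", 0.5),
                    ("q3", 0.75), ("max", 1.0)]
    if n < 5:
        stats_wanted = stats_wanted[:n]
    rows = []
    for name, q in stats_wanted:
        target = float(np.quantile(scores, q))
        dist = np.abs(scores - target)
        best = np.flatnonzero(dist == dist.min())
        if id_col in df.columns:
            ids = df.loc[best, id_col].to_numpy()
            pick = best[np.argmin(ids)]
        else:
            pick = best.min()
        rows.append({
            "statistic": name,
            "target_score": target,
            "score": float(scores[pick]),
            id_col: df.loc[pick, id_col] if id_col in df.columns else int(pick),
            "partial": n < 5,
        })
    return pd.DataFrame(rows)


def compare_models(acc_a, acc_b, equal_var: bool = True):
    """Two-sample two-tailed t-test on repeat accuracies of two models."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 repeats per model")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# histograms and the assembled report
# ---------------------------------------------------------------------------

def pooled_histogram_bins(scores, max_bins: int = 80) -> np.ndarray:
    """Freedman-Diaconis bin edges on the pooled score range.

    All populations are binned identically so their distributions are
    visually comparable.
    """
    s = np.asarray(scores, dtype=float)
    iqr = np.subtract(*np.percentile(s, [75, 25]))
    if iqr <= 0 or len(s) < 2:
        return np.linspace(s.min() - 0.5, s.max() + 0.5, 11)
    width = 2.0 * iqr / np.cbrt(len(s))
    n_bins = int(np.clip(np.ceil(np.ptp(s) / width), 1, max_bins))
    return np.linspace(s.min(), s.max(), n_bins + 1)


@dataclass
class EvaluationReport:
    """Everything the reporting stage writes: tables keyed by model/line."""

    confusion: dict
    accuracy: dict
    roc: dict
    auc: dict
    histograms: dict
    excluded_outliers: list
    correlations: pd.DataFrame
    representatives: dict


def evaluate_scores(
    test_scores: pd.DataFrame,
    transfer_scores: pd.DataFrame,
    outlier_sd: float = 5.6,
) -> EvaluationReport:
    """Assemble the full evaluation from test-set and transfer score tables.

    The outlier rule applies to SVM scores only; other score types are
    reported unfiltered. Histogram counts per line plus its excluded
    outliers always add up to the number of scored cells.
    """
    labeled = test_scores.dropna(subset=["true_class"])
    y_true = labeled["true_class"].to_numpy()
    y_num = np.where(y_true == "M", 1, -1)

    confusion, accuracy, roc_pts, auc_val = {}, {}, {}, {}
    for name, col in [("svm", "svm_score"), ("boost", "boost_score"),
                      ("bag", "bag_posterior")]:
        pred = np.where(
            labeled[col] > (0.5 if name == "bag" else 0.0), "M", "E"
        )
        mat = confusion_matrix(pred, y_true)
        confusion[name] = mat
        accuracy[name] = accuracy_from_confusion(mat)
        pts, a = roc_auc(labeled[col].to_numpy(), y_num, positive=1)
        roc_pts[name] = pts
        auc_val[name] = a

    all_scores = pd.concat([test_scores, transfer_scores], ignore_index=True)
    retained_idx, excluded_idx = exclude_outliers(
        all_scores["svm_score"], sd_threshold=outlier_sd
    )
    retained = all_scores.loc[retained_idx]

    histograms = {}
    for col in ("svm_score", "platt_posterior", "boost_score", "bag_posterior"):
        source = retained if col == "svm_score" else all_scores
        edges = pooled_histogram_bins(source[col].to_numpy())
        per_line = {}
        for line, sub in source.groupby("line"):
            counts, _ = np.histogram(sub[col].to_numpy(), bins=edges)
            per_line[line] = counts
        histograms[col] = {"edges": edges, "counts": per_line}

    correlations = score_correlations(
        all_scores,
        columns=["svm_score", "platt_posterior", "boost_score", "bag_posterior"],
    )

    representatives = {}
    for line, sub in all_scores.groupby("line"):
        if len(sub) >= 1:
            representatives[line] = representative_cells(sub)

    return EvaluationReport(
        confusion=confusion,
        accuracy=accuracy,
        roc=roc_pts,
        auc=auc_val,
        histograms=histograms,
        excluded_outliers=[
            (all_scores.loc[i, "line"], all_scores.loc[i, "cell_id"])
            if "cell_id" in all_scores.columns else i
            for i in excluded_idx
        ],
        correlations=correlations,
        representatives=representatives,
    )
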