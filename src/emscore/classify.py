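"""Binary epithelial/mesenchymal classification and transfer scoring.

The archetype classifier is trained on two reference populations
(epithelial coded −1/"E", mesenchymal +1/"M") after standardizing the 17
phase parameters and projecting onto the leading principal components.
Four per-cell scores are produced and transferred to unknown cells:

* the linear-SVM decision value ``s = (x/s_k)'β + b`` — the signed distance
  of the observation to the separating hyperplane (the EM score proper);
* its Platt posterior ``P(s) = 1 / (1 + exp(A·s + B))``;
* the AdaBoost ensemble score ``f(x) = Σ_t a_t h_t(x)`` with learner
  weights ``a_t = ½·log[(1−ε_t)/ε_t]``;
* the bagged-trees posterior
  ``P̂(c|x) = Σ_t a_t P̂_t(c|x) 1[t∈S] / Σ_t a_t 1[t∈S]``.

Number of retained components defaults to 6 and can be selected by a
repeated-measures ANOVA over cross-validated accuracies with a Dunnett
many-to-one comparison against the single-component model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import SchemaError
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

#: Class coding: epithelial = −1 ("E"), mesenchymal = +1 ("M").
EPITHELIAL, MESENCHYMAL = -1, 1
CLASS_NAMES = {EPITHELIAL: "E", MESENCHYMAL: "M"}


# ---------------------------------------------------------------------------
# data partitioning
# ---------------------------------------------------------------------------

def partition_data(
    table: pd.DataFrame,
    test_n: int = 80,
    seed: int = 0,
    lines: tuple[str, str] = ("GIE", "HGF"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-line random holdout of exactly ``test_n`` cells.

    With the default populations (332 and 309 archetype cells) and
    ``test_n=80`` this leaves 252 + 229 = 481 training cells.
    """
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for line in lines:
        sub = table[table["line"] == line]
        if len(sub) <= test_n:
            raise ValueError(
                f"line {line!r} has {len(sub)} cells; need more than {test_n}"
            )
        perm = rng.permutation(len(sub))
        test_parts.append(sub.iloc[perm[:test_n]])
        train_parts.append(sub.iloc[perm[test_n:]])
    train = pd.concat(train_parts).sort_index()
    test = pd.concat(test_parts).sort_index()
    return train, test


def labels_from_lines(
    table: pd.DataFrame, epithelial_line: str = "GIE", mesenchymal_line: str = "HGF"
) -> np.ndarray:
    """Map archetype line labels to the ±1 class coding."""
    y = np.where(table["line"] == mesenchymal_line, MESENCHYMAL, EPITHELIAL)
    unknown = ~table["line"].isin([epithelial_line, mesenchymal_line])
    if unknown.any():
        raise ValueError("table contains non-archetype lines")
    return y.astype(int)


# ---------------------------------------------------------------------------
# PCA predictor transform
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Standardize-then-project transform of the 17 phase parameters."""

    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray          # (k, n_features), orthonormal rows
    explained_variance: np.ndarray
    k: int
    feature_names: list = field(default_factory=lambda: list(FEATURE_NAMES))


def pca_fit(features, k: int = 6, feature_names=None) -> PCAModel:
    """Fit standardization + PCA on training features only.

    A feature that is constant across the training set gets unit scale (with
    a warning) rather than dividing by zero.
    """
    x, names = _as_matrix(features, feature_names)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a PCA")
    if k > x.shape[1]:
        raise ValueError(f"k={k} exceeds the {x.shape[1]} available features")
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    const = scales == 0
    if const.any():
        warnings.warn(
            f"constant feature(s) {np.nonzero(const)[0].tolist()}: scale set to 1",
            stacklevel=2,
        )
        scales = np.where(const, 1.0, scales)
    z = (x - means) / scales
    sk = _SkPCA(n_components=min(x.shape[1], x.shape[0] - 1), svd_solver="full")
    sk.fit(z)
    return PCAModel(
        means=means,
        scales=scales,
        loadings=sk.components_[:k].copy(),
        explained_variance=sk.explained_variance_[:k].copy(),
        k=k,
        feature_names=names,
    )


def pca_transform(model: PCAModel, features, k: int | None = None) -> np.ndarray:
    """Project features with a fitted transform (no refit)."""
    x, names = _as_matrix(features, model.feature_names)
    if names != model.feature_names:
        raise SchemaError("feature columns do not match the fitted transform")
    k = model.k if k is None else k
    if k > model.loadings.shape[0]:
        raise ValueError("requested more components than were retained")
    z = (x - model.means) / model.scales
    return z @ model.loadings[:k].T


def _as_matrix(features, feature_names):
    if isinstance(features, pd.DataFrame):
        names = feature_names or [c for c in FEATURE_NAMES if c in features.columns]
        missing = [c for c in names if c not in features.columns]
        if missing:
            raise SchemaError(f"missing feature columns: {missing}")
        return features[names].to_numpy(dtype=float), list(names)
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(x.shape[1])]
    return x, names


# ---------------------------------------------------------------------------
# linear SVM and decision-value score
# ---------------------------------------------------------------------------

@dataclass
class LinearSVMModel:
    """Soft-margin linear SVM: score(x) = (x/s_k)'β + b."""

    beta: np.ndarray
    b: float
    kernel_scale: float = 1.0
    C: float = 1.0


def train_linear_svm(
    x: np.ndarray, y: np.ndarray, C: float = 1.0, kernel_scale: float = 1.0
) -> LinearSVMModel:
    """Fit the soft-margin linear SVM on predictors divided by ``s_k``.

    ``kernel_scale`` defaults to 1 (identity); any positive value simply
    rescales the predictor space before the fit.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train an SVM")
    if kernel_scale <= 0:
        raise ValueError("kernel_scale must be positive")
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(x / kernel_scale, y)
    # sklearn orients the decision function toward the larger class label,
    # which is +1 = mesenchymal under our coding.
    beta = clf.coef_.ravel().copy()
    return LinearSVMModel(
        beta=beta, b=float(clf.intercept_[0]), kernel_scale=kernel_scale, C=C
    )


def svm_score(model: LinearSVMModel, x: np.ndarray) -> np.ndarray:
    """Signed distance-to-boundary score ``(x/s_k)'β + b``."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.beta.shape[0]:
        raise ValueError(
            f"expected {model.beta.shape[0]} predictors, got {x.shape[1]}"
        )
    s = (x / model.kernel_scale) @ model.beta + model.b
    return float(s[0]) if single else s


def svm_predict(model: LinearSVMModel, x: np.ndarray) -> np.ndarray:
    """Class prediction from the score sign; ties (s == 0) go epithelial."""
    s = np.atleast_1d(svm_score(model, x))
    return np.where(s > 0, MESENCHYMAL, EPITHELIAL)


# ---------------------------------------------------------------------------
# Platt posterior calibration
# ---------------------------------------------------------------------------

@dataclass
class PlattModel:
    """Sigmoid posterior ``P(s) = 1 / (1 + exp(A·s + B))``.

    ``A < 0`` when larger scores mean higher mesenchymal probability.
    """

    A: float
    B: float


def platt_fit(scores: np.ndarray, labels: np.ndarray) -> PlattModel:
    """Regularized ML fit of the sigmoid (Platt's target coding)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = y == MESENCHYMAL, y == EPITHELIAL
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to fit Platt scaling")
    if np.ptp(s) == 0:
        raise ValueError("degenerate scores: all values identical")
    # Platt (1999) regularized targets
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * s + b
        # P = 1/(1+e^z) = σ(-z); NLL = Σ t·z + log(1+e^{-z}), stable form
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    res = optimize.minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    res = optimize.minimize(nll, x0=res.x, method="Powell",
                            options={"xtol": 1e-12, "ftol": 1e-14})
    return PlattModel(A=float(res.x[0]), B=float(res.x[1]))


def platt_posterior(model: PlattModel, s) -> np.ndarray:
    """Posterior probability of the mesenchymal class at score ``s``."""
    s = np.asarray(s, dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(model.A * s + model.B))


# ---------------------------------------------------------------------------
# decision trees stored as plain arrays (JSON-serializable)
# ---------------------------------------------------------------------------

@dataclass
class _TreePredictor:
    """A fitted decision tree flattened to arrays, with a vectorized walker."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    proba: np.ndarray  # (n_nodes, 2): P(E), P(M) leaf class frequencies

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeClassifier) -> "_TreePredictor":
        t = tree.tree_
        counts = t.value[:, 0, :]  # (n_nodes, n_classes) in tree.classes_ order
        proba = counts / counts.sum(axis=1, keepdims=True)
        classes = list(tree.classes_)
        cols = [classes.index(EPITHELIAL), classes.index(MESENCHYMAL)]
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            proba=proba[:, cols].copy(),
        )

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        node = np.zeros(x.shape[0], dtype=int)
        active = self.children_left[node] >= 0
        while active.any():
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = x[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(
                go_left, self.children_left[nd], self.children_right[nd]
            )
            active = self.children_left[node] >= 0
        return self.proba[node]

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.predict_proba(x)
        return np.where(p[:, 1] > p[:, 0], MESENCHYMAL, EPITHELIAL)

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "proba": self.proba.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_TreePredictor":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=int),
            children_right=np.asarray(d["children_right"], dtype=int),
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=float),
            proba=np.asarray(d["proba"], dtype=float),
        )


# ---------------------------------------------------------------------------
# AdaBoost ensemble
# ---------------------------------------------------------------------------

#: cap on a_t when a learner achieves zero weighted error
A_T_CAP = 0.5 * np.log((1.0 - 1e-10) / 1e-10)


@dataclass
class BoostModel:
    """AdaBoost ensemble of depth-limited trees.

    ``alphas`` stores the closed-form learner weights
    ``a_t = ½·log[(1−ε_t)/ε_t]``; the learning rate shrinks each learner's
    contribution to the reweighting and to the final score sum.
    """

    learners: list
    alphas: np.ndarray
    errors: np.ndarray
    learning_rate: float = 0.1
    T: int = 200


def train_boost(
    x: np.ndarray,
    y: np.ndarray,
    T: int = 200,
    learning_rate: float = 0.1,
    max_depth: int = 3,
    seed: int = 0,
) -> BoostModel:
    """Sequential reweighting AdaBoost with decision-tree weak learners.

    Training stops early if a learner reaches zero weighted error (its
    weight is capped, with a warning) or fails the weak-learning condition
    ``ε_t < 0.5`` (the learner is rejected and training stops, logged).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train AdaBoost")
    n = len(y)
    w = np.full(n, 1.0 / n)
    learners, alphas, errors = [], [], []
    for t in range(T):
        tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed + t)
        tree.fit(x, y, sample_weight=w)
        pred = tree.predict(x)
        miss = pred != y
        eps = float(w[miss].sum() / w.sum())
        if eps >= 0.5:
            logger.info("AdaBoost stopped at t=%d: weighted error %.3f >= 0.5", t, eps)
            break
        if eps <= 0.0:
            warnings.warn(
                f"AdaBoost learner {t} has zero weighted error; "
                f"weight capped at {A_T_CAP:.2f}",
                stacklevel=2,
            )
            a = A_T_CAP
        else:
            a = 0.5 * np.log((1.0 - eps) / eps)
        learners.append(_TreePredictor.from_sklearn(tree))
        alphas.append(a)
        errors.append(eps)
        if eps <= 0.0:
            break
        w = w * np.exp(-learning_rate * a * y * pred)
        w = w / w.sum()
    if not learners:
        raise ValueError("no valid weak learner found")
    return BoostModel(
        learners=learners,
        alphas=np.asarray(alphas),
        errors=np.asarray(errors),
        learning_rate=learning_rate,
        T=T,
    )


def boost_score(model: BoostModel, x: np.ndarray) -> np.ndarray:
    """Ensemble score ``f(x) = Σ_t rate·a_t·h_t(x)``; sign = predicted class."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    f = np.zeros(x.shape[0])
    for a, learner in zip(model.alphas, model.learners):
        f += model.learning_rate * a * learner.predict(x)
    return float(f[0]) if single else f


# ---------------------------------------------------------------------------
# bagged-trees ensemble
# ---------------------------------------------------------------------------

@dataclass
class BagModel:
    """Bootstrap-aggregated trees with the weighted-posterior combination."""

    learners: list
    weights: np.ndarray            # a_t, uniform 1 by default
    included: np.ndarray           # S: inclusion indicators
    T: int = 200
    learning_rate: float = 0.1     # kept as configuration metadata; unused


def train_bag(
    x: np.ndarray,
    y: np.ndarray,
    T: int = 200,
    seed: int = 0,
    learning_rate: float = 0.1,
) -> BagModel:
    """Train ``T`` trees on bootstrap resamples of the training data."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train bagged trees")
    rng = np.random.default_rng(seed)
    n = len(y)
    learners = []
    for t in range(T):
        while True:  # a bootstrap draw must contain both classes
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        tree = DecisionTreeClassifier(random_state=seed + t)
        tree.fit(x[idx], y[idx])
        learners.append(_TreePredictor.from_sklearn(tree))
    return BagModel(
        learners=learners,
        weights=np.ones(T),
        included=np.ones(T, dtype=bool),
        T=T,
        learning_rate=learning_rate,
    )


def bag_posterior(model: BagModel, x: np.ndarray, cls: int = MESENCHYMAL) -> np.ndarray:
    """Weighted mean of included learners' class posteriors.

    ``P̂_bag(c|x) = Σ_t a_t P̂_t(c|x) 1[t∈S] / Σ_t a_t 1[t∈S]``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    col = 1 if cls == MESENCHYMAL else 0
    num = np.zeros(x.shape[0])
    den = 0.0
    for a, inc, learner in zip(model.weights, model.included, model.learners):
        if not inc:
            continue
        num += a * learner.predict_proba(x)[:, col]
        den += a
    if den == 0:
        raise ValueError("no learners included in S")
    p = num / den
    return float(p[0]) if single else p


# ---------------------------------------------------------------------------
# cross-validation and PC-count selection
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-repeat pooled accuracies of a repeated stratified k-fold CV."""

    accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0


def svm_trainer(C: float = 1.0, kernel_scale: float = 1.0):
    """Fit-function factory for :func:`crossvalidate`."""

    def fit(xtr, ytr):
        model = train_linear_svm(xtr, ytr, C=C, kernel_scale=kernel_scale)
        return lambda xte: svm_predict(model, xte)

    return fit


def crossvalidate(
    fit,
    x: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV repeated with fresh shuffles.

    ``fit(xtr, ytr)`` must return a ``predict(xte) -> labels`` callable.
    Each repeat's accuracy pools correct predictions across its folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=int)
    accs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        correct = 0
        for tr_idx, te_idx in skf.split(x, y):
            predict = fit(x[tr_idx], y[tr_idx])
            correct += int(np.sum(np.atleast_1d(predict(x[te_idx])) == y[te_idx]))
        accs.append(correct / len(y))
    return CVResult(accuracies=np.asarray(accs))


def rm_anova(acc_table: np.ndarray) -> tuple[float, float]:
    """One-factor repeated-measures ANOVA on a (repeats × conditions) table.

    Returns (F, p) for the condition effect with the subject (repeat) effect
    removed, computed from explicit sums of squares.
    """
    a = np.asarray(acc_table, dtype=float)
    r, g = a.shape
    if r < 2 or g < 2:
        raise ValueError("need >= 2 repeats and >= 2 conditions")
    grand = a.mean()
    ss_total = float(((a - grand) ** 2).sum())
    ss_cond = float(r * ((a.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(g * ((a.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df_cond, df_err = g - 1, (g - 1) * (r - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if ms_err <= 0:
        return 0.0, 1.0
    f_stat = ms_cond / ms_err
    return float(f_stat), float(stats.f.sf(f_stat, df_cond, df_err))


def dunnett_vs_control(
    acc_table: np.ndarray,
    control: int = 0,
    n_mc: int = 200_000,
    seed: int = 0,
    method: str = "mvt",
) -> pd.DataFrame:
    """Many-to-one comparisons of each condition against a control column.

    Test statistics use the repeated-measures error term; adjusted p-values
    come from the equicorrelated (ρ = 0.5) multivariate-t reference
    distribution of the maximum |t| (Monte Carlo, seeded), or from a
    sign-permutation fallback on the paired differences (``method="perm"``).
    """
    a = np.asarray(acc_table, dtype=float)
    r, g = a.shape
    means = a.mean(axis=0)
    _, _ = rm_anova(a)  # validates shape
    grand = a.mean()
    ss_total = float(((a - grand) ** 2).sum())
    ss_cond = float(r * ((means - grand) ** 2).sum())
    ss_subj = float(g * ((a.mean(axis=1) - grand) ** 2).sum())
    df_err = (g - 1) * (r - 1)
    ms_err = (ss_total - ss_cond - ss_subj) / df_err
    others = [j for j in range(g) if j != control]
    se = np.sqrt(max(2.0 * ms_err / r, 1e-300))
    tvals = np.array([(means[j] - means[control]) / se for j in others])

    rng = np.random.default_rng(seed)
    m = len(others)
    if method == "mvt":
        # max|T| over m equicorrelated (rho=0.5) t variates sharing one
        # chi-square denominator with df_err degrees of freedom
        z0 = rng.standard_normal(n_mc)
        z = rng.standard_normal((n_mc, m))
        zc = np.sqrt(0.5) * z + np.sqrt(0.5) * z0[:, None]
        chi = rng.chisquare(df_err, size=n_mc)
        tmax = np.abs(zc / np.sqrt(chi / df_err)[:, None]).max(axis=1)
        pvals = [(1.0 + np.sum(tmax >= abs(t))) / (n_mc + 1.0) for t in tvals]
    elif method == "perm":
        diffs = a[:, others] - a[:, [control]]
        obs = np.abs(tvals)
        count = np.zeros(m)
        n_perm = min(n_mc, 20_000)
        for _ in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=(r, 1))
            d = diffs * signs
            sd = d.std(axis=0, ddof=1)
            sd = np.where(sd == 0, np.inf, sd)
            tperm = np.abs(d.mean(axis=0) / (sd / np.sqrt(r))).max()
            count += tperm >= obs
        pvals = ((count + 1.0) / (n_perm + 1.0)).tolist()
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {"condition": others, "mean_diff": means[others] - means[control],
         "t": tvals, "p_adj": pvals}
    )


@dataclass
class PCSelectionReport:
    """Cross-validated accuracies by component count, with the test results."""

    candidates: list
    acc_table: np.ndarray      # (repeats, len(candidates))
    f_stat: float
    p_value: float
    dunnett: pd.DataFrame
    k_star: int


def select_pc_count(
    features,
    y: np.ndarray,
    candidates=tuple(range(1, 18)),
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    C: float = 1.0,
) -> tuple[int, PCSelectionReport]:
    """Select the number of principal components by repeated CV + ANOVA.

    The transform is fitted once on the full training set; candidate models
    use its leading ``k`` components, with identical fold shuffles across
    candidates so repeats are paired. ``k*`` is the smallest candidate whose
    improvement over the 1-PC model is significant (Dunnett-adjusted) and
    beyond which no candidate offers a further significant paired gain.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate component counts")
    if repeats < 2:
        raise ValueError("need at least 2 repeats for a repeated-measures test")
    pca = pca_fit(features, k=max(candidates))
    acc = np.zeros((repeats, len(candidates)))
    for j, k in enumerate(candidates):
        xk = pca_transform(pca, features, k=k)
        cv = crossvalidate(svm_trainer(C=C), xk, y, folds=folds, repeats=repeats,
                           seed=seed)
        acc[:, j] = cv.accuracies
    f_stat, p_value = rm_anova(acc)
    dun = dunnett_vs_control(acc, control=0, seed=seed)

    sig = {
        candidates[int(row.condition)]
        for row in dun.itertuples()
        if row.p_adj < alpha and row.mean_diff > 0
    }
    k_star = candidates[0]
    for j, k in enumerate(candidates):
        if k not in sig:
            continue
        gain_beyond = False
        for j2 in range(j + 1, len(candidates)):
            d = acc[:, j2] - acc[:, j]
            sd = d.std(ddof=1)
            if sd == 0:
                continue
            t = d.mean() / (sd / np.sqrt(repeats))
            if d.mean() > 0 and stats.t.sf(t, repeats - 1) * 2 < alpha:
                gain_beyond = True
                break
        if not gain_beyond:
            k_star = k
            break
    report = PCSelectionReport(
        candidates=candidates, acc_table=acc, f_stat=f_stat,
        p_value=p_value, dunnett=dun, k_star=k_star,
    )
    return k_star, report


# ---------------------------------------------------------------------------
# model bundle, training, transfer scoring
# ---------------------------------------------------------------------------

@dataclass
class EMModel:
    """Trained archetype-classifier bundle used to transfer EM scores."""

    pca: PCAModel
    svm: LinearSVMModel
    platt: PlattModel
    boost: BoostModel
    bag: BagModel
    epithelial_line: str = "GIE"
    mesenchymal_line: str = "HGF"
    schema_version: int = 1

    def to_json(self, path) -> None:
        doc = {
            "schema_version": self.schema_version,
            "epithelial_line": self.epithelial_line,
            "mesenchymal_line": self.mesenchymal_line,
            "pca": {
                "means": self.pca.means.tolist(),
                "scales": self.pca.scales.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "explained_variance": self.pca.explained_variance.tolist(),
                "k": self.pca.k,
                "feature_names": list(self.pca.feature_names),
            },
            "svm": {
                "beta": self.svm.beta.tolist(),
                "b": self.svm.b,
                "kernel_scale": self.svm.kernel_scale,
                "C": self.svm.C,
            },
            "platt": {"A": self.platt.A, "B": self.platt.B},
            "boost": {
                "alphas": self.boost.alphas.tolist(),
                "errors": self.boost.errors.tolist(),
                "learning_rate": self.boost.learning_rate,
                "T": self.boost.T,
                "learners": [t.to_dict() for t in self.boost.learners],
            },
            "bag": {
                "weights": self.bag.weights.tolist(),
                "included": self.bag.included.astype(int).tolist(),
                "T": self.bag.T,
                "learning_rate": self.bag.learning_rate,
                "learners": [t.to_dict() for t in self.bag.learners],
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "EMModel":
        with open(path) as fh:
            d = json.load(fh)
        pca = PCAModel(
            means=np.asarray(d["pca"]["means"]),
            scales=np.asarray(d["pca"]["scales"]),
            loadings=np.asarray(d["pca"]["loadings"]),
            explained_variance=np.asarray(d["pca"]["explained_variance"]),
            k=int(d["pca"]["k"]),
            feature_names=list(d["pca"]["feature_names"]),
        )
        svm = LinearSVMModel(
            beta=np.asarray(d["svm"]["beta"]),
            b=float(d["svm"]["b"]),
            kernel_scale=float(d["svm"]["kernel_scale"]),
            C=float(d["svm"]["C"]),
        )
        platt = PlattModel(A=float(d["platt"]["A"]), B=float(d["platt"]["B"]))
        boost = BoostModel(
            learners=[_TreePredictor.from_dict(t) for t in d["boost"]["learners"]],
            alphas=np.asarray(d["boost"]["alphas"]),
            errors=np.asarray(d["boost"]["errors"]),
            learning_rate=float(d["boost"]["learning_rate"]),
            T=int(d["boost"]["T"]),
        )
        bag = BagModel(
            learners=[_TreePredictor.from_dict(t) for t in d["bag"]["learners"]],
            weights=np.asarray(d["bag"]["weights"]),
            included=np.asarray(d["bag"]["included"], dtype=bool),
            T=int(d["bag"]["T"]),
            learning_rate=float(d["bag"]["learning_rate"]),
        )
        return cls(
            pca=pca, svm=svm, platt=platt, boost=boost, bag=bag,
            epithelial_line=d["epithelial_line"],
            mesenchymal_line=d["mesenchymal_line"],
            schema_version=int(d["schema_version"]),
        )


def train_em_model(
    train_table: pd.DataFrame,
    k: int = 6,
    C: float = 1.0,
    kernel_scale: float = 1.0,
    T: int = 200,
    learning_rate: float = 0.1,
    seed: int = 0,
    epithelial_line: str = "GIE",
    mesenchymal_line: str = "HGF",
) -> EMModel:
    """Fit the full archetype bundle (PCA + SVM + Platt + AdaBoost + Bag)."""
    y = labels_from_lines(train_table, epithelial_line, mesenchymal_line)
    pca = pca_fit(train_table, k=k)
    x = pca_transform(pca, train_table)
    svm = train_linear_svm(x, y, C=C, kernel_scale=kernel_scale)
    platt = platt_fit(svm_score(svm, x), y)
    boost = train_boost(x, y, T=T, learning_rate=learning_rate, seed=seed)
    bag = train_bag(x, y, T=T, seed=seed, learning_rate=learning_rate)
    return EMModel(
        pca=pca, svm=svm, platt=platt, boost=boost, bag=bag,
        epithelial_line=epithelial_line, mesenchymal_line=mesenchymal_line,
    )


def transfer_score(model: EMModel, table: pd.DataFrame) -> pd.DataFrame:
    """Score unknown cells with the trained bundle (no refitting).

    Applies the training-fitted standardization and projection, then the
    four scores; class assignment follows the SVM sign convention (score
    > 0 ⇒ mesenchymal "M", otherwise epithelial "E").
    """
    x = pca_transform(model.pca, table)
    s = svm_score(model.svm, x)
    out = pd.DataFrame(
        {
            "svm_score": s,
            "platt_posterior": platt_posterior(model.platt, s),
            "boost_score": boost_score(model.boost, x),
            "bag_posterior": bag_posterior(model.bag, x, MESENCHYMAL),
            "predicted_class": np.where(s > 0, "M", "E"),
        },
        index=table.index,
    )
    for col in ("line", "field_id", "cell_id", "blend_m"):
        if col in table.columns:
            out[col] = table[col]
    if "line" in table.columns:
        truth = table["line"].map(
            {model.epithelial_line: "E", model.mesenchymal_line: "M"}
        )
        out["true_class"] = truth
    return out
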