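"""Independent brute-force oracles used by the test suite.

Each oracle reaches its answer by a route disjoint from the implementation:
direct primal optimization for the SVM, exhaustive grid search for Platt
scaling, pair counting for the AUC, and exhaustive threshold enumeration
for a single decision stump.
"""

import numpy as np
from scipy import optimize

from emscore.classify import MESENCHYMAL


def svm_primal_oracle(x, y, C=1.0):
    """Soft-margin linear SVM by direct primal minimization (SLSQP)."""
    x = np.atleast_2d(x)
    n, d = x.shape

    def objective(p):
        w, xi = p[:d], p[d + 1:]
        return 0.5 * np.dot(w, w) + C * xi.sum()

    cons = [
        {"type": "ineq",
         "fun": lambda p, i=i: y[i] * (x[i] @ p[:d] + p[d]) - 1 + p[d + 1 + i]}
        for i in range(n)
    ] + [{"type": "ineq", "fun": lambda p, i=i: p[d + 1 + i]} for i in range(n)]
    p0 = np.zeros(d + 1 + n)
    res = optimize.minimize(objective, p0, constraints=cons, method="SLSQP",
                            options={"maxiter": 2000, "ftol": 1e-14})
    return res.x[:d], res.x[d]


def platt_grid_oracle(scores, labels, a_range, b_range):
    """Exhaustive grid search of the Platt negative log-likelihood."""
    pos = labels == MESENCHYMAL
    n_pos, n_neg = pos.sum(), (~pos).sum()
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    best, best_ab = np.inf, None
    for a in a_range:
        z = a * scores[None, :] + np.asarray(b_range)[:, None]
        # P = 1/(1+e^z); likelihood of target t at sample weight 1
        nll = np.sum(t * z + np.logaddexp(0.0, -z), axis=1)
        i = int(np.argmin(nll))
        if nll[i] < best:
            best, best_ab = nll[i], (a, b_range[i])
    return best_ab


def best_stump_oracle(x, y, w):
    """Exhaustive search over axis-aligned single-split stumps."""
    best = (np.inf, None)
    for j in range(x.shape[1]):
        order = np.sort(np.unique(x[:, j]))
        cuts = np.concatenate([[order[0] - 1], (order[1:] + order[:-1]) / 2,
                               [order[-1] + 1]])
        for c in cuts:
            for sign in (1, -1):
                pred = np.where(x[:, j] <= c, -sign, sign)
                err = w[pred != y].sum()
                if err < best[0] - 1e-12:
                    best = (err, (j, c, sign))
    return best


def auc_pair_counting(scores, labels):
    """P(random positive outscores random negative); ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def rm_anova_hand(table):
    """Repeated-measures ANOVA F from first-principles sums of squares."""
    a = np.asarray(table, dtype=float)
    r, g = a.shape
    grand = a.mean()
    ss_total = ((a - grand) ** 2).sum()
    ss_cond = r * ((a.mean(axis=0) - grand) ** 2).sum()
    ss_subj = g * ((a.mean(axis=1) - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    return (ss_cond / (g - 1)) / (ss_err / ((g - 1) * (r - 1)))


def t_statistic_hand(a, b):
    """Two-sample pooled-variance t statistic from the textbook formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1)) + ((nb - 1) * b.var(ddof=1))) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
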