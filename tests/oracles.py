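"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — explicit loops, pair counting,
hand-written contingency arithmetic — and shares no code with the
package under test.
"""

import numpy as np


def auc_by_pair_counting(x, y, fold=True):
    """AUC as the fraction of concordant (pos, neg) pairs, ties half."""
    pos = [v for v, label in zip(x, y) if label == 1]
    neg = [v for v, label in zip(x, y) if label == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    a = wins / (len(pos) * len(neg))
    return max(a, 1.0 - a) if fold else a


def chi2_by_contingency(x, y):
    """Chi-squared of per-class feature sums vs class-frequency expectation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    shifted = x - x.min()
    total = shifted.sum()
    if total == 0:
        return 0.0
    stat = 0.0
    for cls in (0, 1):
        observed = shifted[y == cls].sum()
        expected = total * np.mean(y == cls)
        stat += (observed - expected) ** 2 / expected
    return stat


def fstat_by_anova(x, y):
    """Two-group one-way ANOVA F from the sum-of-squares decomposition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    g1, g0 = x[y == 1], x[y == 0]
    grand = x.mean()
    ss_between = len(g1) * (g1.mean() - grand) ** 2 + len(g0) * (g0.mean() - grand) ** 2
    ss_within = ((g1 - g1.mean()) ** 2).sum() + ((g0 - g0.mean()) ** 2).sum()
    if ss_within == 0:
        return 0.0 if ss_between == 0 else 1e12
    return ss_between / (ss_within / (len(x) - 2))


RELEVANCE_ORACLES = {
    "auc": auc_by_pair_counting,
    "chi2": chi2_by_contingency,
    "fstat": fstat_by_anova,
}


def abs_pearson(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return abs(float(np.corrcoef(a, b)[0, 1]))


def stepwise_mrmr(X, y, k, relevance="auc", divisor_exponent=2):
    """Brute-force greedy MRMR: at every step re-evaluate the full
    objective for every remaining feature and take the first argmax."""
    X = np.asarray(X, dtype=float)
    rel_fn = RELEVANCE_ORACLES[relevance]
    n_features = X.shape[1]
    selected: list[int] = []
    for _ in range(k):
        best_j, best_obj = None, -np.inf
        for j in range(n_features):
            if j in selected:
                continue
            rel = rel_fn(X[:, j], y)
            if selected:
                red = sum(abs_pearson(X[:, j], X[:, l]) for l in selected)
                penalty = red / len(selected) ** divisor_exponent
            else:
                penalty = 0.0
            obj = rel - penalty
            if obj > best_obj:
                best_j, best_obj = j, obj
        selected.append(best_j)
    return selected
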