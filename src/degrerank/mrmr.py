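"""Greedy minimum-redundancy-maximum-relevance (MRMR) gene selection.

At each step the non-selected feature maximizing

    relevance(x_j, y) - (1 / |S|^d) * sum_{l in S} redundancy(x_j, x_l)

is added to the selected set S, where relevance is one of a folded ROC
AUC, a chi-squared statistic, or a two-group F-statistic, redundancy is
the absolute Pearson correlation, and the divisor exponent d is 2 by
default (d = 1, the conventional mean-redundancy form, is available as
an option).  The redundancy term is defined as 0 while S is empty.
Ties are broken deterministically by candidate order.

A random-forest feature-importance ranking (:func:`rffi_rank`) is
provided as the standard comparator selector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import chi2 as _sk_chi2

from .dataio import ExpressionMatrix, PhenotypeLabels

__all__ = [
    "MRMRConfig",
    "SelectionTrace",
    "relevance_auc",
    "relevance_chi2",
    "relevance_fstat",
    "relevance_scores",
    "redundancy_pearson",
    "mrmr_select",
    "mrmr_select_arrays",
    "rffi_rank",
]

RELEVANCE_KINDS = ("auc", "chi2", "fstat")

# Returned for a zero-within-variance, unequal-means group split, where the
# F-statistic diverges.
F_STAT_CAP = 1e12


@dataclass(frozen=True)
class MRMRConfig:
    """Configuration of the greedy selector.

    redundancy_norm: "squared_cardinality" divides the accumulated
    redundancy by |S|^2 (the default); "cardinality" divides by |S|,
    the conventional mean-redundancy MRMR form.
    fold_auc: report AUC relevance as max(a, 1-a) so down-regulated
    markers are not penalized; set False for the raw direction-sensitive
    AUC.  abs_corr: use |r| rather than signed r as redundancy.
    """

    k: int
    relevance: str = "auc"
    redundancy_norm: str = "squared_cardinality"
    fold_auc: bool = True
    abs_corr: bool = True
    tie_break: str = "candidate_order"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.relevance not in RELEVANCE_KINDS:
            raise ValueError(f"relevance must be one of {RELEVANCE_KINDS}")
        if self.redundancy_norm not in ("squared_cardinality", "cardinality"):
            raise ValueError("redundancy_norm must be 'squared_cardinality' or 'cardinality'")
        if self.tie_break != "candidate_order":
            raise ValueError("only 'candidate_order' tie-breaking is implemented")

    @property
    def divisor_exponent(self) -> int:
        return 2 if self.redundancy_norm == "squared_cardinality" else 1


@dataclass(frozen=True)
class SelectionTrace:
    """Ordered record of a greedy selection run: the chosen gene at each
    step together with the objective and its relevance / redundancy
    decomposition (step 1 has redundancy 0 by definition)."""

    gene_ids: tuple[str, ...]
    objective: tuple[float, ...]
    relevance: tuple[float, ...]
    redundancy_penalty: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("selection trace contains duplicate genes")
        if not (len(self.objective) == len(self.relevance) == len(self.redundancy_penalty) == n):
            raise ValueError("trace component lengths disagree")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    uniq = np.unique(y)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two classes")
    return (y == uniq.max()).astype(int) if not set(uniq) <= {0, 1} else y.astype(int)


def relevance_auc(x, y, fold: bool = True) -> float:
    """ROC AUC of ranking samples by raw feature value (ties half-weight),
    folded to max(a, 1-a) so the direction of regulation is immaterial."""
    return float(relevance_scores(np.asarray(x, float).reshape(-1, 1), y,
                                  "auc", fold_auc=fold)[0])


def relevance_chi2(x, y) -> float:
    """Chi-squared statistic after shifting the feature to be non-negative
    (class-wise sums vs totals expected under class independence)."""
    return float(relevance_scores(np.asarray(x, float).reshape(-1, 1), y, "chi2")[0])


def relevance_fstat(x, y) -> float:
    """Two-group one-way ANOVA F statistic (between / within mean square)."""
    return float(relevance_scores(np.asarray(x, float).reshape(-1, 1), y, "fstat")[0])


def relevance_scores(X: np.ndarray, y, kind: str, fold_auc: bool = True) -> np.ndarray:
    """Vectorized per-column relevance of samples x features matrix X."""
    X = np.asarray(X, dtype=float)
    yb = _check_binary(y)
    n1 = int(yb.sum())
    n0 = len(yb) - n1
    if kind == "auc":
        ranks = stats.rankdata(X, axis=0)
        u = ranks[yb == 1].sum(axis=0) - n1 * (n1 + 1) / 2.0
        a = u / (n1 * n0)
        return np.maximum(a, 1.0 - a) if fold_auc else a
    if kind == "chi2":
        shifted = X - X.min(axis=0, keepdims=True)
        zero = shifted.sum(axis=0) == 0
        out = np.zeros(X.shape[1])
        if (~zero).any():
            with np.errstate(invalid="ignore", divide="ignore"):
                stat, _ = _sk_chi2(shifted[:, ~zero], yb)
            out[~zero] = np.nan_to_num(stat, nan=0.0)
        return out
    if kind == "fstat":
        if n1 < 2 or n0 < 2:
            raise ValueError("each class needs >= 2 samples for the F-statistic")
        g1, g0 = X[yb == 1], X[yb == 0]
        m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
        grand = X.mean(axis=0)
        ss_between = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
        ss_within = ((g1 - m1) ** 2).sum(axis=0) + ((g0 - m0) ** 2).sum(axis=0)
        ms_between = ss_between  # df = 1 for two groups
        ms_within = ss_within / (len(yb) - 2)
        out = np.empty(X.shape[1])
        degenerate = ms_within == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            out[~degenerate] = ms_between[~degenerate] / ms_within[~degenerate]
        out[degenerate & (ms_between == 0)] = 0.0
        out[degenerate & (ms_between > 0)] = F_STAT_CAP
        return out
    raise ValueError(f"unknown relevance kind {kind!r}")


def redundancy_pearson(x_j, x_l, absolute: bool = True) -> float:
    """Pearson correlation as a redundancy measure; |r| by default, 0 if
    either vector is constant."""
    x_j = np.asarray(x_j, dtype=float)
    x_l = np.asarray(x_l, dtype=float)
    if x_j.shape != x_l.shape:
        raise ValueError("feature vectors must have equal length")
    if x_j.std() == 0 or x_l.std() == 0:
        return 0.0
    r = float(stats.pearsonr(x_j, x_l).statistic)
    return abs(r) if absolute else r


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    """Center and scale columns so that corr = Z.T @ Z; constant columns
    become zero (redundancy 0 with everything)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    norm = np.linalg.norm(Xc, axis=0)
    norm[norm == 0] = np.inf
    return Xc / norm


def mrmr_select_arrays(X: np.ndarray, y, cfg: MRMRConfig,
                       feature_names=None) -> SelectionTrace:
    """Greedy MRMR on a samples x features array (core routine)."""
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    if feature_names is None:
        feature_names = [str(i) for i in range(n_features)]
    if cfg.k > n_features:
        raise ValueError(f"k={cfg.k} exceeds the {n_features} candidate features")
    rel = relevance_scores(X, y, cfg.relevance, fold_auc=cfg.fold_auc)
    Z = _standardize_columns(X)
    d = cfg.divisor_exponent

    selected: list[int] = []
    cum_red = np.zeros(n_features)  # sum of redundancy to selected features
    obj_log, rel_log, pen_log = [], [], []
    available = np.ones(n_features, dtype=bool)
    for _ in range(cfg.k):
        if selected:
            penalty = cum_red / (len(selected) ** d)
        else:
            penalty = np.zeros(n_features)
        objective = rel - penalty
        objective[~available] = -np.inf
        j = int(np.argmax(objective))  # first max = candidate-order tie-break
        selected.append(j)
        available[j] = False
        obj_log.append(float(objective[j]))
        rel_log.append(float(rel[j]))
        pen_log.append(float(penalty[j]))
        r = Z.T @ Z[:, j]
        cum_red += np.abs(r) if cfg.abs_corr else r
    return SelectionTrace(
        tuple(feature_names[j] for j in selected),
        tuple(obj_log), tuple(rel_log), tuple(pen_log),
    )


def mrmr_select(m: ExpressionMatrix, y: PhenotypeLabels, cfg: MRMRConfig) -> SelectionTrace:
    """Greedy MRMR over the genes of an expression matrix."""
    yl = y.reorder(m.sample_ids)
    return mrmr_select_arrays(m.X, yl.y, cfg, feature_names=list(m.gene_ids))


def rffi_rank(m: ExpressionMatrix, y: PhenotypeLabels, k: int,
              n_trees: int = 100, seed: int = 0) -> tuple[str, ...]:
    """Top-k genes by impurity-based random-forest feature importance
    (n_trees trees); deterministic given the seed, ties broken by
    candidate order."""
    if k > m.n_genes:
        raise ValueError(f"k={k} exceeds the {m.n_genes} candidate genes")
    yl = y.reorder(m.sample_ids)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(m.X, yl.y)
    order = np.argsort(-rf.feature_importances_, kind="stable")
    return tuple(m.gene_ids[i] for i in order[:k])
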