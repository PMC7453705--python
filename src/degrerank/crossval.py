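"""Repeated stratified k-fold cross-validation with in-fold feature
selection — the re-ranking engine.

For each of R runs the samples are partitioned into K stratified folds
(per-run seed = base_seed + run index).  Within every iteration the
selector sees ONLY the training portion; the classifier is fitted on
the training samples restricted to the selected genes and scored on the
held-out fold.  Selections are logged per iteration; a gene's
importance score is the fraction of the R*K iterations in which it was
among the top-k selected (85 selections out of 100 iterations -> 0.85).
Performance is reported as the unweighted mean of per-iteration ACC,
Sn, Sp, MCC and AUC, together with a vertically averaged ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .dataio import ExpressionMatrix, PhenotypeLabels
from .mrmr import MRMRConfig, mrmr_select_arrays

__all__ = [
    "CVConfig",
    "SelectionRecord",
    "CVResult",
    "CLASSIFIERS",
    "SELECTORS",
    "stratified_folds",
    "compute_metrics",
    "run_repeated_cv",
    "importance_scores",
    "average_roc",
    "compare_models",
]

CLASSIFIERS = ("random_forest_100", "gradient_boosting_100", "logistic_l2")
SELECTORS = ("mrmr_auc", "mrmr_chi2", "mrmr_fstat", "rffi", "none")

METRIC_NAMES = ("acc", "sn", "sp", "mcc", "auc")


@dataclass(frozen=True)
class CVConfig:
    n_runs: int = 10
    n_folds: int = 10
    k_grid: tuple[int, ...] = tuple(range(1, 11))
    base_seed: int = 0
    classifiers: tuple[str, ...] = ("logistic_l2",)
    selectors: tuple[str, ...] = ("mrmr_auc",)
    redundancy_norm: str = "squared_cardinality"
    roc_grid_size: int = 101

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.n_folds < 2:
            raise ValueError("need n_runs >= 1 and n_folds >= 2")
        if not self.k_grid:
            raise ValueError("k_grid must be non-empty")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")
        for s in self.selectors:
            if s not in SELECTORS:
                raise ValueError(f"unknown selector {s!r}")
        object.__setattr__(self, "k_grid", tuple(int(k) for k in self.k_grid))
        object.__setattr__(self, "classifiers", tuple(self.classifiers))
        object.__setattr__(self, "selectors", tuple(self.selectors))


@dataclass(frozen=True)
class SelectionRecord:
    """One train/test iteration of one (classifier, selector, k) model."""

    run: int
    fold: int
    classifier: str
    selector: str
    k: int
    genes: tuple[str, ...]


@dataclass
class CVResult:
    """Selection log plus aggregated evaluation report.

    ``report`` has one row per (classifier, selector, k) with the mean
    of each metric over the R*K iterations; ``roc_curves`` maps the same
    key to an (fpr_grid, mean_tpr) pair; ``per_iteration`` keeps the raw
    per-iteration metrics for distributional comparisons.
    """

    selection_log: list[SelectionRecord]
    report: pd.DataFrame
    roc_curves: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]]
    per_iteration: pd.DataFrame
    n_iterations: int


def _make_classifier(name: str, seed: int):
    if name == "random_forest_100":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "gradient_boosting_100":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    if name == "logistic_l2":
        # L2 regularization (C=1) is sklearn's default penalty
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def stratified_folds(y: PhenotypeLabels, n_folds: int, seed: int) -> list[tuple[str, ...]]:
    """Partition sample ids into n_folds disjoint stratified subsets, each
    preserving the global class ratio to within one sample."""
    yb = y.y
    minority = min(int(yb.sum()), int(len(yb) - yb.sum()))
    if n_folds > minority:
        raise ValueError(
            f"n_folds={n_folds} exceeds the minority-class count {minority}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = np.asarray(y.sample_ids)
    return [tuple(ids[test]) for _, test in skf.split(np.zeros(len(yb)), yb)]


def _rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Mann-Whitney rank AUC with half-weight ties."""
    n1 = int(y_true.sum())
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(y_score)
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_metrics(y_true, y_pred, y_score) -> dict[str, float]:
    """ACC, Sn, Sp, MCC and AUC from hard predictions and scores.

    Sensitivity is reported on the positive (event) class; MCC is
    defined as 0 when any marginal of the confusion matrix is empty.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if not (len(y_true) == len(y_pred) == len(y_score)):
        raise ValueError("input lengths differ")
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    tn = float(np.sum((y_true == 0) & (y_pred == 0)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return {
        "acc": (tp + tn) / n,
        "sn": tp / (tp + fn) if tp + fn else 0.0,
        "sp": tn / (tn + fp) if tn + fp else 0.0,
        "mcc": float(mcc),
        "auc": _rank_auc(y_true, y_score),
    }


def _select_order(selector: str, Xtr: np.ndarray, ytr: np.ndarray,
                  gene_ids: tuple[str, ...], k_max: int, seed: int,
                  redundancy_norm: str) -> tuple[str, ...]:
    """Ordered top-k_max genes from the training portion only.

    Greedy MRMR is nested, so the length-k_max trace yields the top-k
    prefix for every k <= k_max.
    """
    if selector == "none":
        return gene_ids[:k_max]
    if selector == "rffi":
        rf = RandomForestClassifier(n_estimators=100, random_state=seed)
        rf.fit(Xtr, ytr)
        order = np.argsort(-rf.feature_importances_, kind="stable")
        return tuple(gene_ids[i] for i in order[:k_max])
    kind = selector.removeprefix("mrmr_")
    cfg = MRMRConfig(k=k_max, relevance=kind, redundancy_norm=redundancy_norm)
    return mrmr_select_arrays(Xtr, ytr, cfg, feature_names=gene_ids).gene_ids


def _iteration_seed(base_seed: int, run: int, fold: int) -> int:
    return (base_seed * 9973 + run * 101 + fold) % (2**31 - 1)


def run_repeated_cv(m: ExpressionMatrix, y: PhenotypeLabels, cfg: CVConfig) -> CVResult:
    """R runs of stratified K-fold CV with per-fold selection and training.

    Every output is fully determined by (inputs, cfg.base_seed).
    """
    yl = y.reorder(m.sample_ids)
    yb = yl.y
    X = m.X
    gene_ids = m.gene_ids
    k_max = max(cfg.k_grid)
    if k_max > len(gene_ids):
        raise ValueError(f"max k={k_max} exceeds {len(gene_ids)} candidate genes")
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    sample_pos = {s: i for i, s in enumerate(m.sample_ids)}

    log: list[SelectionRecord] = []
    rows: list[dict] = []
    curves: dict[tuple[str, str, int], list[tuple[np.ndarray, np.ndarray]]] = {}

    for run in range(cfg.n_runs):
        folds = stratified_folds(yl, cfg.n_folds, cfg.base_seed + run)
        for fold_idx, test_ids in enumerate(folds):
            test = np.asarray([sample_pos[s] for s in test_ids])
            train = np.setdiff1d(np.arange(len(yb)), test)
            Xtr, ytr = X[train], yb[train]
            Xte, yte = X[test], yb[test]
            if ytr.sum() in (0, len(ytr)) or yte.sum() in (0, len(yte)):
                raise ValueError("a fold lost one of the classes")
            it_seed = _iteration_seed(cfg.base_seed, run, fold_idx)
            for selector in cfg.selectors:
                order = _select_order(selector, Xtr, ytr, gene_ids, k_max,
                                      it_seed, cfg.redundancy_norm)
                for k in cfg.k_grid:
                    genes = order[:k]
                    idx = [gene_pos[g] for g in genes]
                    for clf_name in cfg.classifiers:
                        clf = _make_classifier(clf_name, it_seed)
                        clf.fit(Xtr[:, idx], ytr)
                        score = clf.predict_proba(Xte[:, idx])[:, 1]
                        pred = (score >= 0.5).astype(int)
                        mets = compute_metrics(yte, pred, score)
                        fpr, tpr, _ = roc_curve(yte, score)
                        key = (clf_name, selector, k)
                        curves.setdefault(key, []).append((fpr, tpr))
                        rows.append(
                            {"run": run, "fold": fold_idx, "classifier": clf_name,
                             "selector": selector, "k": k, **mets}
                        )
                        log.append(SelectionRecord(run, fold_idx, clf_name,
                                                   selector, k, tuple(genes)))

    per_iter = pd.DataFrame(rows)
    report = (
        per_iter.groupby(["classifier", "selector", "k"], sort=False)[list(METRIC_NAMES)]
        .mean()
        .reset_index()
    )
    roc_out = {
        key: average_roc(clist, grid_size=cfg.roc_grid_size)[:2]
        for key, clist in curves.items()
    }
    return CVResult(log, report, roc_out, per_iter, cfg.n_runs * cfg.n_folds)


def importance_scores(result: CVResult, classifier: str, selector: str, k: int,
                      gene_ids=None) -> pd.DataFrame:
    """Selection-frequency importance for one (classifier, selector, k)
    combination: count of iterations in which each gene was selected,
    and count / n_iterations as a score in [0, 1].  Genes never selected
    are retained with score 0 when ``gene_ids`` supplies the universe.
    """
    entries = [r for r in result.selection_log
               if r.classifier == classifier and r.selector == selector and r.k == k]
    if not entries:
        raise KeyError(f"no log entries for ({classifier}, {selector}, k={k})")
    counts: dict[str, int] = {}
    for rec in entries:
        for g in rec.genes:
            counts[g] = counts.get(g, 0) + 1
    universe = list(gene_ids) if gene_ids is not None else sorted(counts)
    n_iter = len(entries)
    df = pd.DataFrame(
        {
            "gene_id": universe,
            "count": [counts.get(g, 0) for g in universe],
        }
    )
    df["score"] = df["count"] / n_iter
    return df


def average_roc(curves, grid_size: int = 101):
    """Vertical averaging of ROC step curves on a fixed FPR grid.

    Each curve is treated as a right-continuous step function of FPR
    (TPR at grid point f = TPR of the last ROC vertex with FPR <= f);
    the averaged curve's trapezoidal AUC is also returned.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one ROC curve to average")
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs = np.empty((len(curves), grid_size))
    for i, (fpr, tpr) in enumerate(curves):
        fpr = np.asarray(fpr, dtype=float)
        tpr = np.asarray(tpr, dtype=float)
        # index of the last vertex with fpr <= f; vertex TPRs are the
        # maxima attained at that FPR, so this is the conservative step.
        idx = np.searchsorted(fpr, grid, side="right") - 1
        idx = np.clip(idx, 0, len(fpr) - 1)
        tprs[i] = tpr[idx]
    mean_tpr = tprs.mean(axis=0)
    auc = float(np.trapezoid(mean_tpr, grid))
    return grid, mean_tpr, auc


def compare_models(auc_samples_a, auc_samples_b) -> float:
    """Two-sided Mann-Whitney U p-value between two AUC distributions
    (exact without ties for n, m <= 12; tie-corrected normal
    approximation otherwise)."""
    a = np.asarray(auc_samples_a, dtype=float)
    b = np.asarray(auc_samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both AUC sample lists must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size <= 12 and b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)
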