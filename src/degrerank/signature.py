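"""Minimal gene-signature search over an importance-ranked gene list.

Given the selection-frequency ranking produced by repeated CV, evaluate
the top-k panels over a k range and pick the smallest panel whose mean
AUC and high-specificity partial AUC are both within epsilon of the best
observed — an operational form of "no further improvement in the ROC
curve", with the leftmost (specificity > floor) region weighted because
that is where competitive clinical models are told apart.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .crossval import CVConfig, CVResult, run_repeated_cv, average_roc
from .dataio import ExpressionMatrix, PhenotypeLabels

__all__ = [
    "SignatureResult",
    "rank_by_importance",
    "partial_auc",
    "evaluate_signature",
    "minimal_signature",
    "compare_rankings",
]


@dataclass
class SignatureResult:
    chosen_k: int
    gene_ids: tuple[str, ...]
    per_k: pd.DataFrame  # columns: k, mean_auc, partial_auc
    report: CVResult  # full evaluation of the chosen set, all classifiers


def rank_by_importance(table: pd.DataFrame) -> list[str]:
    """Genes sorted by importance score descending (ties by gene_id);
    genes never selected (score 0) are dropped."""
    if table.empty:
        raise ValueError("importance table is empty")
    nz = table.loc[table["score"] > 0]
    nz = nz.sort_values(["score", "gene_id"], ascending=[False, True], kind="stable")
    return nz["gene_id"].tolist()


def partial_auc(fpr: np.ndarray, tpr: np.ndarray, max_fpr: float) -> float:
    """Trapezoidal area under the ROC restricted to FPR <= max_fpr,
    normalized by the maximum attainable area (so it lives in [0, 1])."""
    if not 0 < max_fpr <= 1:
        raise ValueError("max_fpr must be in (0, 1]")
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    mask = fpr <= max_fpr
    f, t = fpr[mask], tpr[mask]
    if f[-1] < max_fpr:  # close the region at max_fpr by interpolation
        t_end = np.interp(max_fpr, fpr, tpr)
        f = np.append(f, max_fpr)
        t = np.append(t, t_end)
    return float(np.trapezoid(t, f) / max_fpr)


def _fixed_set_cfg(cfg: CVConfig, n_genes: int, classifiers=None) -> CVConfig:
    return replace(
        cfg,
        selectors=("none",),
        k_grid=(n_genes,),
        classifiers=tuple(classifiers) if classifiers is not None else cfg.classifiers,
    )


def evaluate_signature(m: ExpressionMatrix, y: PhenotypeLabels, genes,
                       cfg: CVConfig) -> CVResult:
    """Repeated CV of a FIXED gene panel (no in-fold selection) with all
    configured classifiers; unknown gene ids are reported by name."""
    genes = list(genes)
    sub = m.subset_genes(genes)  # raises KeyError naming unknown genes
    return run_repeated_cv(sub, y, _fixed_set_cfg(cfg, len(genes)))


def minimal_signature(m: ExpressionMatrix, y: PhenotypeLabels, ranked,
                      k_range, cfg: CVConfig, epsilon: float = 0.005,
                      spec_floor: float = 0.80) -> SignatureResult:
    """Smallest top-k panel within epsilon of the best mean AUC AND the
    best normalized partial AUC over the specificity > spec_floor region.

    The search uses the first configured classifier; the chosen panel is
    then re-evaluated with every configured classifier.
    """
    ranked = list(ranked)
    k_range = [int(k) for k in k_range]
    if not k_range:
        raise ValueError("k_range is empty")
    if max(k_range) > len(ranked):
        raise ValueError(f"k={max(k_range)} exceeds the {len(ranked)} ranked genes")
    search_clf = cfg.classifiers[0]
    max_fpr = 1.0 - spec_floor

    rows = []
    for k in sorted(k_range):
        res = run_repeated_cv(
            m.subset_genes(ranked[:k]), y, _fixed_set_cfg(cfg, k, [search_clf])
        )
        mean_auc = float(res.report["auc"].iloc[0])
        grid, mean_tpr = res.roc_curves[(search_clf, "none", k)]
        rows.append({"k": k, "mean_auc": mean_auc,
                     "partial_auc": partial_auc(grid, mean_tpr, max_fpr)})
    per_k = pd.DataFrame(rows)

    best_auc = per_k["mean_auc"].max()
    best_pauc = per_k["partial_auc"].max()
    ok = (per_k["mean_auc"] >= best_auc - epsilon) & (
        per_k["partial_auc"] >= best_pauc - epsilon
    )
    if ok.any():
        chosen_k = int(per_k.loc[ok, "k"].min())
    else:
        # The AUC and partial-AUC optima can disagree by more than epsilon;
        # fall back to the mean-AUC rule alone.
        chosen_k = int(per_k.loc[per_k["mean_auc"] >= best_auc - epsilon, "k"].min())
    genes = tuple(ranked[:chosen_k])
    final = evaluate_signature(m, y, genes, cfg)
    return SignatureResult(chosen_k, genes, per_k, final)


def compare_rankings(m: ExpressionMatrix, y: PhenotypeLabels,
                     rankings: dict[str, list], k: int, cfg: CVConfig):
    """Paired evaluation of the top-k genes of several rankings with the
    same CV partitions (shared base seed), plus overlap bookkeeping.

    Returns (reports, overlap) where ``reports`` maps ranking name to its
    CVResult and ``overlap`` holds pairwise intersection sizes and the
    set of genes common to all rankings.
    """
    tops: dict[str, tuple[str, ...]] = {}
    for name, genes in rankings.items():
        genes = list(genes)
        if len(genes) < k:
            raise ValueError(f"ranking {name!r} has fewer than k={k} genes")
        tops[name] = tuple(genes[:k])
    reports = {
        name: evaluate_signature(m, y, top, cfg) for name, top in tops.items()
    }
    names = list(tops)
    pairwise = {
        (a, b): len(set(tops[a]) & set(tops[b]))
        for i, a in enumerate(names) for b in names[i + 1:]
    }
    common = set.intersection(*(set(t) for t in tops.values())) if tops else set()
    overlap = {"pairwise": pairwise, "common": sorted(common)}
    return reports, overlap
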