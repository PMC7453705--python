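"""Two-group differential expression on log2 expression values.

Produces the DEG table that feeds the re-ranking stage: per-gene log2
fold change (positive-class mean minus negative-class mean), signed fold
change, Welch t-test p-value, Benjamini-Hochberg adjusted p-value and
regulation direction.  The built-in test is Welch's unequal-variance t;
externally computed tables (e.g. limma output) can be imported instead
via :func:`import_deg_table`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix, PhenotypeLabels

__all__ = [
    "log_fold_change",
    "signed_fold_change",
    "welch_t_test",
    "bh_adjust",
    "build_deg_table",
    "filter_degs",
    "import_deg_table",
    "write_deg_table",
]

DEG_COLUMNS = ["gene_id", "log_fc", "fc", "p_value", "adj_p_value", "regulation"]


def _split(m: ExpressionMatrix, y: PhenotypeLabels) -> tuple[np.ndarray, np.ndarray]:
    yl = y.reorder(m.sample_ids)
    mask = yl.y.astype(bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both phenotype classes must be non-empty")
    return m.values[:, mask], m.values[:, ~mask]


def log_fold_change(m: ExpressionMatrix, y: PhenotypeLabels) -> np.ndarray:
    """Per-gene mean difference on the log2 scale, positive minus negative
    class — up-regulated means higher in the positive (event) group."""
    pos, neg = _split(m, y)
    return pos.mean(axis=1) - neg.mean(axis=1)


def signed_fold_change(log_fc) -> np.ndarray | float:
    """Signed linear fold change: sign(log_fc) * 2**|log_fc|.

    Negative values encode down-regulation; |fc| >= 1 always, and
    log_fc = 0 maps to +1.0.
    """
    lfc = np.asarray(log_fc, dtype=float)
    fc = np.where(lfc >= 0, 2.0 ** lfc, -(2.0 ** (-lfc)))
    fc = np.where(lfc == 0, 1.0, fc)
    return fc if fc.ndim else float(fc)


def welch_t_test(m: ExpressionMatrix, y: PhenotypeLabels) -> np.ndarray:
    """Two-sided Welch unequal-variance t-test per gene.

    Degenerate genes (zero variance in both groups) get p = 1 when the
    group means agree and p = 0 when they differ.
    """
    pos, neg = _split(m, y)
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples for Welch's t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(pos, neg, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (pos.var(axis=1) == 0) & (neg.var(axis=1) == 0)
    if degenerate.any():
        equal = np.isclose(pos.mean(axis=1), neg.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        bad = int(np.argmax((p < 0) | (p > 1) | ~np.isfinite(p)))
        raise ValueError(f"p-value out of [0, 1] at position {bad}: {p[bad]}")
    return multipletests(p, method="fdr_bh")[1]


def build_deg_table(m: ExpressionMatrix, y: PhenotypeLabels) -> pd.DataFrame:
    """Full per-gene DE table (unfiltered), ordered as the input matrix."""
    lfc = log_fold_change(m, y)
    p = welch_t_test(m, y)
    return pd.DataFrame(
        {
            "gene_id": list(m.gene_ids),
            "log_fc": lfc,
            "fc": signed_fold_change(lfc),
            "p_value": p,
            "adj_p_value": bh_adjust(p),
            "regulation": np.where(lfc > 0, "up", "down"),
        }
    )


def filter_degs(table: pd.DataFrame, fc_threshold: float = 1.5,
                adjp_threshold: float = 0.05) -> pd.DataFrame:
    """Keep genes with |fc| >= fc_threshold and adj_p <= adjp_threshold
    (both thresholds inclusive); row order preserved."""
    if fc_threshold <= 0 or adjp_threshold <= 0:
        raise ValueError("thresholds must be positive")
    keep = (table["fc"].abs() >= fc_threshold) & (table["adj_p_value"] <= adjp_threshold)
    return table.loc[keep].reset_index(drop=True)


def import_deg_table(path, delimiter: str | None = None) -> pd.DataFrame:
    """Load an externally computed DE table (e.g. limma topTable output).

    Columns are matched case-insensitively against common aliases; at
    least one of fc / log_fc must be present, and the other is
    reconstructed (log_fc = sign(fc) * log2|fc|).  If both are present
    they must agree to 1e-6.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    if delimiter is not None:
        sep = delimiter
    df = pd.read_csv(path, sep=sep)
    aliases = {
        "gene_id": {"gene_id", "gene", "id", "symbol"},
        "log_fc": {"log_fc", "logfc", "log2fc", "log2foldchange"},
        "fc": {"fc", "fold_change", "foldchange"},
        "p_value": {"p_value", "pvalue", "p.value", "p"},
        "adj_p_value": {"adj_p_value", "adj.p.val", "adj_p", "padj", "fdr", "qvalue"},
    }
    found: dict[str, str] = {}
    for canon, names in aliases.items():
        for col in df.columns:
            if str(col).strip().lower() in names:
                found[canon] = col
                break
    missing = [c for c in ("gene_id", "p_value", "adj_p_value") if c not in found]
    if "fc" not in found and "log_fc" not in found:
        missing.append("fc or log_fc")
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")

    out = pd.DataFrame({"gene_id": df[found["gene_id"]].astype(str)})
    if "log_fc" in found:
        out["log_fc"] = pd.to_numeric(df[found["log_fc"]]).astype(float)
    if "fc" in found:
        fc = pd.to_numeric(df[found["fc"]]).to_numpy(dtype=float)
        lfc_from_fc = np.sign(fc) * np.log2(np.abs(fc))
        if "log_fc" in out:
            if np.max(np.abs(out["log_fc"].to_numpy() - lfc_from_fc)) > 1e-6:
                raise ValueError("fc and log_fc columns are inconsistent")
        else:
            out["log_fc"] = lfc_from_fc
    out["fc"] = signed_fold_change(out["log_fc"].to_numpy())
    out["p_value"] = pd.to_numeric(df[found["p_value"]]).astype(float)
    out["adj_p_value"] = pd.to_numeric(df[found["adj_p_value"]]).astype(float)
    out["regulation"] = np.where(out["log_fc"] > 0, "up", "down")
    return out[DEG_COLUMNS]


def write_deg_table(table: pd.DataFrame, path) -> None:
    table[DEG_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")
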