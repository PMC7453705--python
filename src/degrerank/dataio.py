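"""Plain-text I/O for expression matrices, phenotype labels and probe maps.

The universal input is a genes-in-rows, samples-in-columns matrix of
log2-scale expression values (gcRMA-style output).  No normalization is
performed here: values are assumed already log2-normalized upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_probe_map",
    "aggregate_probes",
]

# Full round-trip precision for TSV output.
_FLOAT_FMT = "%.17g"


def _detect_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of continuous log2 expression values.

    Invariants enforced on construction: unique gene and sample ids,
    no missing values, and shape consistent with the id lists.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"shape {values.shape} inconsistent with "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        for name, ids in (("gene", genes), ("sample", samples)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValueError(f"duplicate {name} id {dup!r}")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing or non-finite value at gene {genes[bad[0]]!r}, "
                f"sample {samples[bad[1]]!r}"
            )
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def X(self) -> np.ndarray:
        """Samples x genes view (the classifier orientation)."""
        return self.values.T

    def gene_index(self, gene_ids) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = []
        for g in gene_ids:
            if g not in pos:
                raise KeyError(f"unknown gene id {g!r}")
            idx.append(pos[g])
        return np.asarray(idx, dtype=int)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            tuple(self.gene_ids[i] for i in idx), self.sample_ids, self.values[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())


@dataclass(frozen=True)
class PhenotypeLabels:
    """Binary phenotype per sample; ``positive_class`` is the class of
    interest (e.g. non-survivors) on which sensitivity is reported."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    positive_class: str

    def __post_init__(self) -> None:
        samples = tuple(str(s) for s in self.sample_ids)
        labels = tuple(str(v) for v in self.labels)
        if len(samples) != len(labels):
            raise ValueError("sample_ids and labels length mismatch")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids in labels")
        classes = set(labels)
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 classes, found {sorted(classes)}")
        if str(self.positive_class) not in classes:
            raise ValueError(
                f"positive_class {self.positive_class!r} not among observed "
                f"labels {sorted(classes)}"
            )
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positive_class", str(self.positive_class))

    @property
    def y(self) -> np.ndarray:
        """Binary vector: 1 for the positive class, 0 otherwise."""
        return np.asarray([1 if v == self.positive_class else 0 for v in self.labels])

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    def reorder(self, sample_ids) -> "PhenotypeLabels":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples without labels: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return PhenotypeLabels(
            tuple(sample_ids), tuple(self.labels[i] for i in idx), self.positive_class
        )


def read_expression(path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples matrix (first column gene ids, header sample ids).

    Delimiter is auto-detected from the extension (.csv comma, else tab)
    and can be overridden.  Duplicated ids, missing values and non-numeric
    cells are rejected with the offending row or column named.
    """
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric cell at gene {df.index[bad.argmax()]!r}, "
                f"sample {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        gi, si = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    return ExpressionMatrix.from_frame(df)


def write_expression(m: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    sep = _detect_delimiter(path, delimiter)
    m.to_frame().to_csv(path, sep=sep, float_format=_FLOAT_FMT, index_label="gene_id")


def read_labels(path, positive_class: str | None = None,
                delimiter: str | None = None) -> PhenotypeLabels:
    """Read a two-column (sample_id, label) file.

    If ``positive_class`` is not given, the minority class is used — the
    convention for outcome studies where the event (e.g. death) is rare.
    """
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file must have two columns: sample_id, label")
    samples = df.iloc[:, 0].tolist()
    labels = df.iloc[:, 1].tolist()
    if positive_class is None:
        counts = pd.Series(labels).value_counts()
        positive_class = counts.index[-1]  # minority (ties: later in count order)
    return PhenotypeLabels(tuple(samples), tuple(labels), str(positive_class))


def write_labels(yl: PhenotypeLabels, path, delimiter: str | None = None) -> None:
    sep = _detect_delimiter(path, delimiter)
    pd.DataFrame({"sample_id": list(yl.sample_ids), "label": list(yl.labels)}).to_csv(
        path, sep=sep, index=False
    )


def read_probe_map(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a two-column (probe_id, gene_id) map.

    A probe mapping to more than one gene is ambiguous and rejected.
    """
    sep = _detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map must have two columns: probe_id, gene_id")
    df = df.iloc[:, :2]
    df.columns = ["probe_id", "gene_id"]
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"probe id {dup.iloc[0]!r} maps to multiple genes")
    return df


def aggregate_probes(m: ExpressionMatrix, probe_map: pd.DataFrame) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by the per-sample mean of a
    gene's probes.  Unmapped probes are dropped (counted in a log message);
    output gene order follows first appearance among the mapped probes.
    """
    mapping = dict(zip(probe_map["probe_id"], probe_map["gene_id"]))
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    n_unmapped = 0
    for i, probe in enumerate(m.gene_ids):
        gene = mapping.get(probe)
        if gene is None:
            n_unmapped += 1
            continue
        if gene not in rows:
            rows[gene] = []
            order.append(gene)
        rows[gene].append(i)
    if not order:
        raise ValueError("no probe of the matrix appears in the probe map")
    if n_unmapped:
        logger.info("aggregate_probes: dropped %d unmapped probes", n_unmapped)
    values = np.vstack([m.values[rows[g]].mean(axis=0) for g in order])
    return ExpressionMatrix(tuple(order), m.sample_ids, values)
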