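"""Reading, writing and preprocessing of expression and companion tables.

Expression matrices are genes x samples, delimited text with a header row of
sample identifiers and gene identifiers in the first column.  Standardization
is always performed within a dataset (per-gene z-score), never by reusing
means/variances from another cohort.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_probe_map",
    "collapse_probes",
    "standardize",
    "read_clinical",
    "read_mutations",
    "read_purity",
    "read_labels",
]


@dataclass
class ExpressionMatrix:
    """A gene x sample real-valued matrix with identifier bookkeeping.

    Parameters
    ----------
    data:
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Values must be finite floats.
    standardized:
        True once per-gene z-scoring has been applied.  Guards against
        silent double scaling.
    """

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        dup_genes = idx[idx.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene identifiers: {dup_genes}")
        dup_samples = cols[cols.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample identifiers: {dup_samples}")
        if self.data.isna().any().any():
            bad = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise ValueError(
                f"missing values in rows for genes: {bad[:20]}"
                + (" ..." if len(bad) > 20 else "")
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[genes], standardized=self.standardized)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], standardized=self.standardized)


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples delimited text matrix.

    Non-numeric cells raise with the offending gene/sample location;
    duplicated identifiers raise naming the duplicates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    try:
        data = raw.astype(float)
    except ValueError:
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna()
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {raw.index[gi]!r}, sample "
            f"{raw.columns[si]!r}: {raw.iat[gi, si]!r}"
        ) from None
    return ExpressionMatrix(data)


def write_expression(expr: ExpressionMatrix, path: str | Path, delimiter: str | None = None) -> None:
    """Write to delimited text with full float precision (round-trip safe)."""
    sep = _infer_delimiter(path, delimiter)
    expr.data.to_csv(path, sep=sep, float_format="%.17g")


def read_probe_map(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read a probe -> gene map (two columns: probe_id, gene_id)."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, gene_id")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        raise ValueError(
            f"probes mapped to multiple genes: {probes[probes.duplicated()].tolist()}"
        )
    return pd.Series(genes.to_numpy(), index=probes.to_numpy())


def collapse_probes(expr: ExpressionMatrix, probe_map: pd.Series | dict) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    For each gene with several probes, the probe with the highest mean
    intensity across samples is retained and the others discarded.  Probes
    absent from the map are dropped (count logged).
    """
    pm = pd.Series(probe_map)
    probes = expr.data.index
    mapped = probes[probes.isin(pm.index)]
    n_unmapped = len(probes) - len(mapped)
    if n_unmapped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_unmapped)
    if len(mapped) == 0:
        raise ValueError("no probes in the matrix are present in the probe map")
    sub = expr.data.loc[mapped]
    row_means = sub.mean(axis=1)
    genes = pm.loc[mapped]
    # probe with maximal row mean wins; ties broken by probe order
    best = (
        pd.DataFrame({"gene": genes.to_numpy(), "mean": row_means.to_numpy()}, index=mapped)
        .groupby("gene", sort=False)["mean"]
        .idxmax()
    )
    out = sub.loc[best.to_numpy()]
    out.index = best.index
    return ExpressionMatrix(out, standardized=expr.standardized)


def standardize(expr: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Per-gene z-score (sample sd, ``ddof=1``) within this dataset.

    Zero-variance genes become all-zero rows (kept so that gene indices stay
    aligned with signature lists).  Re-standardizing raises: double scaling
    is a silent bug.
    """
    if expr.standardized:
        raise ValueError("matrix is already standardized; refusing to scale twice")
    vals = expr.values.astype(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.info("standardize: %d zero-variance genes set to zero rows", int(flat.sum()))
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    z[flat, :] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(z, index=expr.data.index, columns=expr.data.columns),
        standardized=True,
    )


def read_clinical(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a clinical table with columns sample_id, survival_time, event.

    Extra columns (external classifications and such) pass through as strings.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "survival_time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    df = df.set_index("sample_id")
    df["survival_time"] = df["survival_time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["survival_time"] < 0).any():
        raise ValueError("negative survival_time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return df


def read_mutations(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a binary gene x sample mutation matrix (0 = wild type, 1 = mutated)."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("mutation matrix must contain only 0/1")
    return df.astype(int)


def read_purity(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read per-sample purity scores (columns: sample_id, purity), values in [0, 1]."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns or "purity" not in df.columns:
        raise ValueError("purity table needs columns sample_id, purity")
    s = pd.Series(df["purity"].astype(float).to_numpy(), index=df["sample_id"].astype(str))
    if ((s < 0) | (s > 1)).any():
        raise ValueError("purity values must lie in [0, 1]")
    return s


def read_labels(path: str | Path, column: str = "consensus_class", delimiter: str | None = None) -> pd.Series:
    """Read per-sample class labels from a calls table (sample_id + label column)."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError("labels table needs a sample_id column")
    if column not in df.columns:
        raise ValueError(f"labels table has no column {column!r}")
    return pd.Series(df[column].astype(str).to_numpy(), index=df["sample_id"].astype(str))
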