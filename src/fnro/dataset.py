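"""Expression-matrix container, file readers and preprocessing.

The pipeline operates on :class:`ExpressionDataset`: a samples x genes real
matrix with integer class codes per sample.  Preprocessing follows the
standard microarray recipe — mean imputation of missing entries, per-gene
Z-score standardization, lexicographic label encoding — applied to the full
dataset before any selection or cross-validation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from .exceptions import DomainError, FormatError, SchemaError, StateError

#: tokens recognized as missing in delimited files (ARFF uses "?")
MISSING_TOKENS = ("", "NA", "NaN")


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with class labels.

    Attributes
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Expression values; missing entries are NaN until imputed.
    gene_ids : list of str
        One unique identifier per column, in column order.
    labels : ndarray of int
        Per-sample class code in ``{0..n_classes-1}``.
    class_names : list of str
        Original label strings in code order (lexicographically sorted).
    meta : dict
        Free-form provenance (source path, preprocessing applied,
        ``constant_genes`` flags, imputation counts).
    """

    values: np.ndarray
    gene_ids: list
    labels: np.ndarray
    class_names: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.values.shape
        if n != len(self.labels):
            raise DomainError(
                f"{n} rows but {len(self.labels)} labels"
            )
        if p != len(self.gene_ids):
            raise DomainError(
                f"{p} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != p:
            raise DomainError("gene_ids must be unique")
        m = len(self.class_names)
        if m < 2:
            raise DomainError("need at least 2 classes")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= m or len(present) != m:
            raise DomainError(
                "every class code in {0..m-1} must appear at least once"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())


def encode_labels(raw_labels: Sequence) -> tuple[np.ndarray, list]:
    """Encode arbitrary labels as dense integer codes 0..m-1.

    Distinct labels are sorted (lexicographically for strings, numerically
    for numbers) and assigned codes in that order, so the encoding is
    deterministic across runs and platforms.

    Returns ``(codes, class_names)`` where ``class_names[i]`` is the string
    form of the label mapped to code ``i``.
    """
    arr = np.asarray(list(raw_labels))
    if arr.size == 0:
        raise DomainError("empty label vector")
    names, codes = np.unique(arr, return_inverse=True)
    if len(names) < 2:
        raise DomainError(
            f"need at least 2 distinct classes, got {len(names)}"
        )
    return codes.astype(int), [str(v) for v in names]


def impute_mean(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace each missing entry by the mean of its gene column.

    Observed entries are never altered; the operation is idempotent.  The
    number of imputed entries is recorded in ``meta['n_imputed']``.  A gene
    column with no observed values has no mean and raises
    :class:`DomainError`.
    """
    values = ds.values.copy()
    nan_mask = np.isnan(values)
    n_imputed = int(nan_mask.sum())
    if n_imputed:
        all_missing = nan_mask.all(axis=0)
        if all_missing.any():
            bad = [ds.gene_ids[j] for j in np.flatnonzero(all_missing)]
            raise DomainError(f"gene columns entirely missing: {bad[:5]}")
        col_means = np.nanmean(values, axis=0)
        rows, cols = np.nonzero(nan_mask)
        values[rows, cols] = col_means[cols]
    meta = dict(ds.meta)
    meta["n_imputed"] = n_imputed
    return replace(ds, values=values, meta=meta)


def zscore_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize each gene column to mean 0, population sd 1.

    Uses the population standard deviation (divide by n).  Constant columns
    are mapped to all zeros and their indices recorded in
    ``meta['constant_genes']`` rather than dropped, keeping gene indices
    stable.  Requires complete data — impute first.
    """
    if ds.has_missing():
        raise StateError("dataset has missing entries; run impute_mean first")
    mu = ds.values.mean(axis=0)
    sigma = ds.values.std(axis=0)  # population sd (ddof=0)
    constant = sigma == 0.0
    safe_sigma = np.where(constant, 1.0, sigma)
    values = (ds.values - mu) / safe_sigma
    values[:, constant] = 0.0
    meta = dict(ds.meta)
    meta["constant_genes"] = [int(j) for j in np.flatnonzero(constant)]
    meta["normalized"] = True
    return replace(ds, values=values, meta=meta)


def _read_arff(path: Path, label_column) -> tuple[pd.DataFrame, pd.Series]:
    try:
        data, arff_meta = scipy_arff.loadarff(str(path))
    except Exception as exc:  # scipy raises several parse error types
        raise FormatError(f"could not parse ARFF file {path}: {exc}") from exc
    df = pd.DataFrame(data)
    # nominal attributes come back as bytes
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.decode("utf-8")
    if isinstance(label_column, int):
        if not -len(df.columns) <= label_column < len(df.columns):
            raise SchemaError(f"label column index {label_column} out of range")
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise SchemaError(f"label column {label_column!r} not in ARFF attributes")
        label_name = label_column
    labels = df[label_name]
    genes = df.drop(columns=[label_name])
    # nominal "?" decodes to "?" — treat as missing in labels is not allowed
    return genes, labels


def _read_delimited(path: Path, label_column) -> tuple[pd.DataFrame, pd.Series]:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            na_values=list(MISSING_TOKENS),
            keep_default_na=False,
        )
    except Exception as exc:
        raise FormatError(f"could not parse delimited file {path}: {exc}") from exc
    if isinstance(label_column, int):
        if not -len(df.columns) <= label_column < len(df.columns):
            raise SchemaError(f"label column index {label_column} out of range")
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise SchemaError(f"label column {label_column!r} not in header")
        label_name = label_column
    labels = df[label_name]
    genes = df.drop(columns=[label_name])
    for col in genes.columns:
        try:
            genes[col] = pd.to_numeric(genes[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"non-numeric token in gene column {col!r}: {exc}"
            ) from exc
    return genes, labels


def read_dataset(path, format: str | None = None, label_column="label") -> ExpressionDataset:
    """Read an expression dataset from ARFF or delimited text.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"arff", "delimited", None}
        ``None`` infers from the extension (``.arff`` vs anything else).
    label_column : str or int
        Name (or positional index) of the class-label column.

    Missing markers ("?" in ARFF; empty string, "NA", "NaN" in delimited)
    become NaN entries, never zeros.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    if format is None:
        format = "arff" if path.suffix.lower() == ".arff" else "delimited"
    if format == "arff":
        genes, labels = _read_arff(path, label_column)
    elif format == "delimited":
        genes, labels = _read_delimited(path, label_column)
    else:
        raise FormatError(f"unknown format {format!r}")
    if labels.isna().any():
        raise SchemaError("label column contains missing values")
    values = genes.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise DomainError("need at least 2 samples")
    codes, class_names = encode_labels(labels.astype(str).tolist())
    return ExpressionDataset(
        values=values,
        gene_ids=[str(c) for c in genes.columns],
        labels=codes,
        class_names=class_names,
        meta={"source": str(path), "format": format},
    )


def preprocess(ds: ExpressionDataset) -> ExpressionDataset:
    """Full preprocessing chain: mean imputation then Z-score normalization."""
    return zscore_normalize(impute_mean(ds))


def write_dataset(ds: ExpressionDataset, path) -> None:
    """Write a dataset back as CSV with a ``label`` column (round-trip form)."""
    df = pd.DataFrame(ds.values, columns=ds.gene_ids)
    df.insert(0, "label", [ds.class_names[c] for c in ds.labels])
    df.to_csv(path, index=False)


def parse_arff_string(text: str, label_column="label") -> ExpressionDataset:
    """Parse an ARFF document held in a string (convenience for tests)."""
    buf = io.StringIO(text)
    try:
        data, _ = scipy_arff.loadarff(buf)
    except Exception as exc:
        raise FormatError(f"could not parse ARFF text: {exc}") from exc
    df = pd.DataFrame(data)
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.decode("utf-8")
    if label_column not in df.columns:
        raise SchemaError(f"label column {label_column!r} not in ARFF attributes")
    labels = df[label_column]
    genes = df.drop(columns=[label_column])
    codes, class_names = encode_labels(labels.astype(str).tolist())
    return ExpressionDataset(
        values=genes.to_numpy(dtype=float),
        gene_ids=[str(c) for c in genes.columns],
        labels=codes,
        class_names=class_names,
        meta={"source": "<string>", "format": "arff"},
    )
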