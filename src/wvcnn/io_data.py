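"""Read and write labeled expression matrices as delimited text.

File format: header row; first column holds the sample identifier; one
designated column holds the class label as a string; every remaining column
is a numeric probe intensity.  ``.csv`` files are comma-delimited, ``.tsv``
tab-delimited.  Floats are printed at full repr precision so a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigurationError,
    DatasetBundle,
    ExpressionMatrix,
    LabelVector,
    ValidationError,
)

DEFAULT_LABEL_COLUMN = "type"


def _delimiter_for(path: str) -> str:
    return "\t" if str(path).lower().endswith(".tsv") else ","


def read_dataset(
    path: str,
    layout: str = "samples_as_rows",
    label_column: str = DEFAULT_LABEL_COLUMN,
    impute_median: bool = False,
) -> DatasetBundle:
    """Load a labeled expression matrix from a CSV/TSV file.

    Parameters
    ----------
    path
        Delimited-text file with a header row and sample/feature ids.
    layout
        ``"samples_as_rows"`` (wide probe-column layout) or
        ``"features_as_rows"`` (probes as rows; transposed on load so the
        in-memory matrix is always samples x features).
    label_column
        Name of the column (or row, for ``features_as_rows``) holding the
        class label strings.
    impute_median
        If True, missing expression cells are filled with the per-feature
        median.  By default missing values are an error.

    Returns
    -------
    DatasetBundle
        Validated bundle.  The class vocabulary is the lexicographically
        sorted set of distinct label strings, mapped to 0-based indices.
    """
    if layout not in ("samples_as_rows", "features_as_rows"):
        raise ConfigurationError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0, dtype=str)
    if layout == "features_as_rows":
        df = df.T
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not found; columns start with "
            f"{list(df.columns[:5])}"
        )
    if df.shape[0] == 0:
        raise ValidationError("empty dataset: no samples")

    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample ids")

    label_strings = df[label_column].astype(str).tolist()
    expr_df = df.drop(columns=[label_column])
    feature_ids = [str(c) for c in expr_df.columns]

    values = np.empty(expr_df.shape, dtype=np.float64)
    for j, col in enumerate(expr_df.columns):
        raw = expr_df[col].to_numpy(dtype=object)
        try:
            # exact strtod parsing; pd.to_numeric's fast path is lossy
            values[:, j] = raw.astype(np.float64)
        except (ValueError, TypeError):
            for i, v in enumerate(raw):
                if pd.isna(v):
                    continue
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise ValidationError(
                        "non-numeric expression value at sample "
                        f"{sample_ids[i]!r}, feature {col!r}"
                    ) from None
            raise

    if np.isnan(values).any():
        if impute_median:
            medians = np.nanmedian(values, axis=0)
            nan_rows, nan_cols = np.nonzero(np.isnan(values))
            values[nan_rows, nan_cols] = medians[nan_cols]
        else:
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing expression value at sample {sample_ids[i]!r}, "
                f"feature {feature_ids[j]!r} (enable impute_median to fill)"
            )

    class_names = sorted(set(label_strings))
    name_to_idx = {c: i for i, c in enumerate(class_names)}
    labels = np.array([name_to_idx[s] for s in label_strings], dtype=np.int64)

    return DatasetBundle(
        ExpressionMatrix(values, feature_ids, sample_ids),
        LabelVector(labels, class_names),
    )


def write_dataset(
    bundle: DatasetBundle,
    path: str,
    label_column: str = DEFAULT_LABEL_COLUMN,
) -> None:
    """Write a bundle as a samples-as-rows delimited file.

    Floats are serialized via ``repr`` (shortest exact representation), so
    ``read_dataset(write_dataset(b))`` reproduces the values bit-exactly.
    """
    if label_column in bundle.expression.feature_ids:
        raise ConfigurationError(
            f"label column name {label_column!r} collides with a feature id"
        )
    sep = _delimiter_for(path)
    expr = bundle.expression
    with open(path, "w", encoding="utf-8") as fh:
        header = ["sample_id", label_column, *expr.feature_ids]
        fh.write(sep.join(header) + "\n")
        names = bundle.labels.as_names()
        for i, sid in enumerate(expr.sample_ids):
            row = [sid, names[i]]
            row.extend(repr(float(v)) for v in expr.values[i])
            fh.write(sep.join(row) + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
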