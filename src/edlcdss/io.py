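"""Reading and writing CKD-style tables in CSV and ARFF.

The UCI chronic kidney disease table is distributed as ARFF; clinical
exports are typically CSV.  Both dialects use ``"?"`` (or an empty cell)
as the missing marker; in memory missing cells become ``NaN``.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from .schema import (
    CATEGORICAL,
    NUMERIC,
    Dataset,
    FeatureSchema,
    SchemaError,
)

#: column names recognised as the class attribute when none is specified
DEFAULT_CLASS_COLUMNS = ("class", "classification")

MISSING_MARKERS = ("?", "")


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the declared dialect."""


def _find_class_column(columns: list[str], class_column: str | None) -> str:
    if class_column is not None:
        if class_column not in columns:
            raise SchemaError(f"class column {class_column!r} not found in table")
        return class_column
    lowered = {c.lower().strip(): c for c in columns}
    for candidate in DEFAULT_CLASS_COLUMNS:
        if candidate in lowered:
            return lowered[candidate]
    raise SchemaError(
        f"no class column found; expected one of {DEFAULT_CLASS_COLUMNS} "
        "or pass class_column explicitly"
    )


def _infer_schema(
    df: pd.DataFrame,
    class_col: str,
    positive_label: str,
    negative_label: str,
    kinds: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, FeatureSchema]:
    """Coerce columns to numeric where possible and build the schema."""
    feature_cols = [c for c in df.columns if c != class_col]
    out = {}
    inferred_kinds: dict[str, str] = {}
    categories: dict[str, tuple[str, ...]] = {}
    for col in feature_cols:
        series = df[col]
        declared = None if kinds is None else kinds.get(col)
        as_num = pd.to_numeric(series, errors="coerce")
        numeric_ok = as_num.notna().equals(series.notna())
        if declared == NUMERIC or (declared is None and numeric_ok):
            out[col] = as_num.astype(float)
            inferred_kinds[col] = NUMERIC
        else:
            vals = series.astype("string")
            out[col] = vals
            inferred_kinds[col] = CATEGORICAL
            levels = sorted({str(v) for v in vals.dropna().unique()})
            if len(levels) < 2:
                # single observed level: pad with an explicit "other" level so
                # the schema invariant (>=2 levels) holds
                levels = levels + ["__other__"]
            categories[col] = tuple(levels)
    schema = FeatureSchema(
        names=tuple(feature_cols),
        kinds=inferred_kinds,
        categories=categories,
        positive_label=positive_label,
        negative_label=negative_label,
    )
    return pd.DataFrame(out, columns=feature_cols), schema


def read_table(
    path: str | Path,
    format: str | None = None,
    class_column: str | None = None,
    positive_label: str = "ckd",
    negative_label: str = "notckd",
) -> Dataset:
    """Read a CSV or ARFF clinical table into a :class:`Dataset`.

    ``"?"`` and empty cells are treated as missing.  The class column is
    located by name (default: ``class`` or ``classification``,
    case-insensitive); its levels must match ``positive_label`` /
    ``negative_label`` after whitespace stripping.

    Parameters
    ----------
    path : path-like
    format : {"csv", "arff"}, optional
        Inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    format = format.lower()
    if format == "csv":
        df = _read_csv(path)
    elif format == "arff":
        df = _read_arff(path)
    else:
        raise FormatError(f"unknown format {format!r}; expected 'csv' or 'arff'")

    class_col = _find_class_column(list(df.columns), class_column)
    X, schema = _infer_schema(df, class_col, positive_label, negative_label)
    y_raw = df[class_col].astype("string").str.strip()
    if y_raw.isna().any():
        missing_rows = list(np.flatnonzero(y_raw.isna().to_numpy())[:5])
        raise SchemaError(f"rows {missing_rows} have no class label")
    return Dataset(X=X, y=y_raw.to_numpy(dtype=object), schema=schema,
                   provenance=str(path))


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            dtype=str,
            na_values=list(MISSING_MARKERS),
            keep_default_na=False,
            skipinitialspace=True,
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate column names in header")
    df.columns = [str(c).strip() for c in df.columns]
    return df.apply(lambda s: s.str.strip() if s.dtype == object else s)


def _read_arff(path: Path) -> pd.DataFrame:
    try:
        data, meta = scipy_arff.loadarff(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as ARFF: {exc}") from exc
    df = pd.DataFrame(data)
    out = {}
    for col in df.columns:
        s = df[col]
        if s.dtype == object:  # nominal: bytes, b'?' marks missing
            s = s.str.decode("utf-8").str.strip()
            s = s.mask(s == "?")
            out[col] = s
        else:
            out[col] = s.astype(float).astype(object).where(s.notna())
    res = pd.DataFrame(out)
    # everything as string for uniform downstream inference
    for col in res.columns:
        res[col] = res[col].map(
            lambda v: v if v is None or (isinstance(v, float) and np.isnan(v))
            else str(v)
        )
    return res.astype("string")


def write_table(ds: Dataset, path: str | Path, format: str | None = None) -> None:
    """Write a dataset to CSV or ARFF, with ``"?"`` marking missing cells."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    format = format.lower()
    if format == "csv":
        _write_csv(ds, path)
    elif format == "arff":
        _write_arff(ds, path)
    else:
        raise FormatError(f"unknown format {format!r}; expected 'csv' or 'arff'")


def _cell_str(v) -> str:
    if pd.isna(v):
        return "?"
    if isinstance(v, float) and v == int(v) and abs(v) < 1e15:
        return repr(v)
    return str(v)


def _write_csv(ds: Dataset, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(ds.schema.names) + ["class"])
        for i in range(len(ds)):
            row = [_cell_str(v) for v in ds.X.iloc[i]]
            writer.writerow(row + [str(ds.y[i])])


def _arff_quote(level: str) -> str:
    if any(ch in level for ch in " ,{}'\"%"):
        return "'" + level.replace("'", r"\'") + "'"
    return level


def _write_arff(ds: Dataset, path: Path) -> None:
    schema = ds.schema
    buf = _io.StringIO()
    buf.write("@relation edlcdss\n\n")
    for name in schema.names:
        if schema.kinds[name] == NUMERIC:
            buf.write(f"@attribute {_arff_quote(name)} numeric\n")
        else:
            levels = ",".join(_arff_quote(l) for l in schema.categories[name])
            buf.write(f"@attribute {_arff_quote(name)} {{{levels}}}\n")
    classes = ",".join(
        _arff_quote(l) for l in (schema.positive_label, schema.negative_label)
    )
    buf.write(f"@attribute class {{{classes}}}\n\n@data\n")
    for i in range(len(ds)):
        cells = [_cell_str(v) for v in ds.X.iloc[i]]
        buf.write(",".join(cells + [str(ds.y[i])]) + "\n")
    Path(path).write_text(buf.getvalue())
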