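"""Core data containers for CKD-style tabular clinical datasets.

A :class:`Dataset` couples a feature table (mixed numeric/categorical, with
explicit missing values) to a binary diagnosis label vector and a
:class:`FeatureSchema` describing each attribute.  Every stage of the
pipeline — file ingestion, preprocessing, rebalancing, model training —
consumes and produces these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NUMERIC = "numeric"
CATEGORICAL = "categorical"

#: default class-level names used by the UCI chronic kidney disease table
POSITIVE_LABEL = "ckd"
NEGATIVE_LABEL = "notckd"


class SchemaError(ValueError):
    """Raised when a table does not conform to its declared schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Describes the predictor attributes of a clinical table.

    Parameters
    ----------
    names : list of str
        Ordered attribute identifiers (class attribute excluded).
    kinds : dict
        Maps each attribute name to ``"numeric"`` or ``"categorical"``.
    categories : dict
        For each categorical attribute, its admissible level set (ordered).
    positive_label, negative_label : str
        Class level names; the positive level denotes disease presence.
    """

    names: tuple[str, ...]
    kinds: dict[str, str]
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)
    positive_label: str = POSITIVE_LABEL
    negative_label: str = NEGATIVE_LABEL

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(
            self, "categories", {k: tuple(v) for k, v in self.categories.items()}
        )
        for name in self.names:
            kind = self.kinds.get(name)
            if kind not in (NUMERIC, CATEGORICAL):
                raise SchemaError(f"attribute {name!r} has invalid kind {kind!r}")
            if kind == CATEGORICAL and len(self.categories.get(name, ())) < 2:
                raise SchemaError(
                    f"categorical attribute {name!r} needs at least 2 levels"
                )
        if self.positive_label == self.negative_label:
            raise SchemaError("class levels must be distinct")

    @property
    def numeric_names(self) -> list[str]:
        return [n for n in self.names if self.kinds[n] == NUMERIC]

    @property
    def categorical_names(self) -> list[str]:
        return [n for n in self.names if self.kinds[n] == CATEGORICAL]

    @property
    def class_labels(self) -> tuple[str, str]:
        return (self.positive_label, self.negative_label)


@dataclass
class Dataset:
    """Feature table + labels + schema.

    ``X`` is a :class:`pandas.DataFrame` whose columns follow
    ``schema.names``; missing cells are ``NaN`` (the in-memory missing
    sentinel — never a numeric stand-in such as ``-999``).  ``y`` is a
    string array over ``{positive_label, negative_label}``.
    """

    X: pd.DataFrame
    y: np.ndarray
    schema: FeatureSchema
    provenance: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=object)
        if len(self.X) != len(self.y):
            raise SchemaError(
                f"feature table has {len(self.X)} rows but {len(self.y)} labels"
            )
        if len(self.X) < 1:
            raise SchemaError("dataset must contain at least one row")
        if list(self.X.columns) != list(self.schema.names):
            raise SchemaError("table columns do not match schema attribute order")
        valid = set(self.schema.class_labels)
        bad = sorted({str(v) for v in self.y if v not in valid})
        if bad:
            raise SchemaError(
                f"unknown class level(s) {bad}; expected one of {sorted(valid)}"
            )

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_missing(self) -> int:
        return int(self.X.isna().to_numpy().sum())

    @property
    def class_counts(self) -> dict[str, int]:
        pos = self.schema.positive_label
        neg = self.schema.negative_label
        return {
            pos: int(np.sum(self.y == pos)),
            neg: int(np.sum(self.y == neg)),
        }

    def y_binary(self) -> np.ndarray:
        """Labels as ints: 1 = positive (disease), 0 = negative."""
        return (self.y == self.schema.positive_label).astype(int)

    def subset(self, idx: np.ndarray, provenance: str | None = None) -> "Dataset":
        """Row subset by positional indices (copy)."""
        idx = np.asarray(idx)
        return Dataset(
            X=self.X.iloc[idx].reset_index(drop=True).copy(),
            y=self.y[idx].copy(),
            schema=self.schema,
            provenance=provenance if provenance is not None else self.provenance,
        )

    def with_provenance(self, tag: str) -> "Dataset":
        return replace(self, provenance=tag)
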