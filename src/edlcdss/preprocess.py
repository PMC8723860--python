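"""Leakage-free preprocessing of mixed clinical tables.

:class:`TablePreprocessor` is a fit/transform estimator in the sklearn
style: all statistics (per-column medians/modes, observed min/max, level
maps) are learned in :meth:`fit` — on training rows only — and applied
unchanged by :meth:`transform`, so held-out rows never influence the
transform.  Output tables are fully numeric with every column in [0, 1],
as required by the downstream models (the deep belief network treats
inputs as Bernoulli visible probabilities).

Conventions
-----------
* numeric: impute (median by default), then min–max scale to [0, 1] using
  the observed training min/max; values outside the training range are
  clipped; a constant column maps to all zeros.
* binary categorical: single {0, 1} column (level order from the schema).
* k-level categorical (k > 2): one-hot columns, one per schema level; an
  unseen level at transform time maps to the all-zero "other" code and is
  logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import CATEGORICAL, NUMERIC, Dataset, FeatureSchema

logger = logging.getLogger(__name__)

NUMERIC_IMPUTE_STRATEGIES = ("median", "mean")
CATEGORICAL_IMPUTE_STRATEGIES = ("mode",)
SCALING_STRATEGIES = ("minmax",)
ENCODING_STRATEGIES = ("onehot",)


class AllMissingColumnError(ValueError):
    """A column with no observed values cannot be imputed."""


class TablePreprocessor(BaseEstimator, TransformerMixin):
    """Impute, scale and encode a :class:`Dataset` into numeric [0, 1] form.

    Parameters
    ----------
    numeric_impute : {"median", "mean"}
    categorical_impute : {"mode"}
    scaling : {"minmax"}
    encoding : {"onehot"}

    Attributes
    ----------
    numeric_stats_ : dict
        Per numeric column: fill value, observed min, observed max.
    level_maps_ : dict
        Per categorical column: level -> encoded column/value.
    feature_names_out_ : list of str
    schema_out_ : FeatureSchema
        All-numeric schema of transformed datasets.
    """

    def __init__(
        self,
        numeric_impute: str = "median",
        categorical_impute: str = "mode",
        scaling: str = "minmax",
        encoding: str = "onehot",
    ):
        self.numeric_impute = numeric_impute
        self.categorical_impute = categorical_impute
        self.scaling = scaling
        self.encoding = encoding

    def _validate_params_(self) -> None:
        for value, allowed, name in (
            (self.numeric_impute, NUMERIC_IMPUTE_STRATEGIES, "numeric_impute"),
            (self.categorical_impute, CATEGORICAL_IMPUTE_STRATEGIES,
             "categorical_impute"),
            (self.scaling, SCALING_STRATEGIES, "scaling"),
            (self.encoding, ENCODING_STRATEGIES, "encoding"),
        ):
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")

    def fit(self, ds: Dataset, y=None) -> "TablePreprocessor":
        self._validate_params_()
        schema = ds.schema
        self.numeric_stats_: dict[str, dict[str, float]] = {}
        self.modes_: dict[str, str] = {}
        for col in schema.numeric_names:
            vals = pd.to_numeric(ds.X[col], errors="coerce").dropna()
            if vals.empty:
                raise AllMissingColumnError(
                    f"numeric column {col!r} has no observed values"
                )
            fill = float(vals.median() if self.numeric_impute == "median"
                         else vals.mean())
            self.numeric_stats_[col] = {
                "fill": fill,
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        for col in schema.categorical_names:
            observed = ds.X[col].dropna()
            if observed.empty:
                raise AllMissingColumnError(
                    f"categorical column {col!r} has no observed values"
                )
            # mode; ties broken by level order for determinism
            counts = observed.value_counts()
            top = counts[counts == counts.iloc[0]].index
            order = {l: i for i, l in enumerate(schema.categories[col])}
            self.modes_[col] = min(top, key=lambda l: order.get(str(l), len(order)))

        names_out: list[str] = []
        for col in schema.names:
            if schema.kinds[col] == NUMERIC:
                names_out.append(col)
            else:
                levels = schema.categories[col]
                if len(levels) == 2:
                    names_out.append(col)
                else:
                    names_out.extend(f"{col}={lvl}" for lvl in levels)
        self.feature_names_out_ = names_out
        self.schema_in_ = schema
        self.schema_out_ = FeatureSchema(
            names=tuple(names_out),
            kinds={n: NUMERIC for n in names_out},
            categories={},
            positive_label=schema.positive_label,
            negative_label=schema.negative_label,
        )
        return self

    def transform(self, ds: Dataset) -> Dataset:
        if not hasattr(self, "numeric_stats_"):
            raise RuntimeError("TablePreprocessor is not fitted")
        if tuple(ds.schema.names) != tuple(self.schema_in_.names):
            raise ValueError("dataset schema does not match the fitted schema")
        schema = self.schema_in_
        cols: dict[str, np.ndarray] = {}
        n = len(ds)
        for col in schema.names:
            if schema.kinds[col] == NUMERIC:
                stats = self.numeric_stats_[col]
                v = pd.to_numeric(ds.X[col], errors="coerce").to_numpy(float)
                v = np.where(np.isnan(v), stats["fill"], v)
                rng = stats["max"] - stats["min"]
                if rng > 0:
                    v = np.clip((v - stats["min"]) / rng, 0.0, 1.0)
                else:
                    v = np.zeros(n)  # constant-column convention
                cols[col] = v
            else:
                levels = schema.categories[col]
                raw = ds.X[col].astype(object).to_numpy()
                raw = np.array(
                    [self.modes_[col] if pd.isna(v) else str(v) for v in raw],
                    dtype=object,
                )
                known = set(levels)
                unseen = sorted({v for v in raw if v not in known})
                if unseen:
                    logger.warning(
                        "column %r: unseen level(s) %s mapped to 'other' code",
                        col, unseen,
                    )
                if len(levels) == 2:
                    # binary -> {0,1}; unseen levels take the 0 ("other") code
                    cols[col] = np.array(
                        [1.0 if v == levels[1] else 0.0 for v in raw]
                    )
                else:
                    for lvl in levels:
                        cols[f"{col}={lvl}"] = (raw == lvl).astype(float)
        X = pd.DataFrame(cols, columns=self.feature_names_out_)
        return Dataset(
            X=X,
            y=ds.y.copy(),
            schema=self.schema_out_,
            provenance=f"{ds.provenance}|preprocessed",
        )

    def fit_transform(self, ds: Dataset, y=None) -> Dataset:
        return self.fit(ds).transform(ds)


def preprocess(ds: Dataset, cfg: TablePreprocessor | None = None
               ) -> tuple[Dataset, TablePreprocessor]:
    """Fit a preprocessor on ``ds`` and return (transformed dataset, fitted
    transform record)."""
    prep = cfg if cfg is not None else TablePreprocessor()
    out = prep.fit_transform(ds)
    return out, prep
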