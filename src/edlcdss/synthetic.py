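"""Seeded generator of CKD-like tabular datasets.

Emulates the statistical shape of the UCI chronic kidney disease table —
400 records, 24 mixed numeric/categorical predictors, a 250:150 class
imbalance and scattered missing values — so the whole pipeline can be
exercised end-to-end without any download.

Numeric predictors are class-conditional Gaussians with unit variance
whose means differ between classes by ``class_separation`` (a
standardized effect size).  Categorical predictors draw their levels from
class-dependent probability tables.  Missingness is applied independently
per predictor cell; labels are never masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import CATEGORICAL, NUMERIC, Dataset, FeatureSchema


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults mirror the UCI CKD table shape."""

    n_positive: int = 250
    n_negative: int = 150
    d_numeric: int = 11
    d_categorical: int = 13
    class_separation: float = 2.5
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_positive + self.n_negative < 1:
            raise ValueError("at least one sample required")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.d_numeric + self.d_categorical < 1:
            raise ValueError("at least one predictor required")


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Draw a dataset according to ``spec``; identical spec -> identical data."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_positive + spec.n_negative
    y = np.array(
        ["ckd"] * spec.n_positive + ["notckd"] * spec.n_negative, dtype=object
    )
    is_pos = y == "ckd"

    cols: dict[str, object] = {}
    names: list[str] = []
    kinds: dict[str, str] = {}
    categories: dict[str, tuple[str, ...]] = {}

    # numeric block: feature-specific baseline, +class_separation shift for
    # the disease class, unit variance
    base = rng.uniform(-1.0, 1.0, size=spec.d_numeric)
    for j in range(spec.d_numeric):
        name = f"num{j:02d}"
        mu = np.where(is_pos, base[j] + spec.class_separation, base[j])
        cols[name] = rng.normal(mu, 1.0)
        names.append(name)
        kinds[name] = NUMERIC

    # categorical block: alternating binary / 3-level attributes whose level
    # probabilities shift with the class; association strength saturates with
    # the configured separation
    delta = min(0.4, 0.15 * spec.class_separation)
    for j in range(spec.d_categorical):
        name = f"cat{j:02d}"
        if j % 2 == 0:
            levels = ("no", "yes")
            p_yes = np.where(is_pos, 0.5 + delta, 0.5 - delta)
            draw = rng.random(n) < p_yes
            cols[name] = np.where(draw, "yes", "no").astype(object)
        else:
            levels = ("low", "mid", "high")
            p_pos = np.array([0.2 - delta / 3, 0.3, 0.5 + delta / 3])
            p_neg = np.array([0.5 + delta / 3, 0.3, 0.2 - delta / 3])
            lv = np.empty(n, dtype=object)
            idx_pos = rng.choice(3, size=int(is_pos.sum()), p=p_pos / p_pos.sum())
            idx_neg = rng.choice(3, size=int((~is_pos).sum()),
                                 p=p_neg / p_neg.sum())
            lv[is_pos] = np.array(levels, dtype=object)[idx_pos]
            lv[~is_pos] = np.array(levels, dtype=object)[idx_neg]
            cols[name] = lv
        names.append(name)
        kinds[name] = CATEGORICAL
        categories[name] = levels

    X = pd.DataFrame(cols, columns=names)
    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = X.mask(pd.DataFrame(mask, columns=X.columns))

    schema = FeatureSchema(names=tuple(names), kinds=kinds, categories=categories)
    tag = (f"synthetic(n={spec.n_positive}+{spec.n_negative}, "
           f"sep={spec.class_separation}, miss={spec.missing_rate}, "
           f"seed={spec.seed})")
    return Dataset(X=X, y=y, schema=schema, provenance=tag)
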