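"""Stratified train/test partitioning.

Thin wrappers over sklearn's stratified splitters operating on
:class:`~edlcdss.schema.Dataset` row indices; per-fold class proportions
stay within one sample of the global proportions.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit


class SplitError(ValueError):
    """A class is too small for the requested partition scheme."""


def split_stratified(
    ds,
    scheme: str = "holdout",
    fraction: float = 0.25,
    k: int = 5,
    seed: int = 0,
):
    """Partition dataset rows with class stratification.

    Parameters
    ----------
    scheme : {"holdout", "kfold"}
        ``holdout`` returns one ``(train_idx, test_idx)`` pair with
        ``fraction`` of rows held out; ``kfold`` returns a list of ``k``
        such pairs (disjoint, exhaustive test sets).
    """
    y = ds.y_binary()
    counts = np.bincount(y, minlength=2)
    if scheme == "kfold":
        if counts.min() < k:
            raise SplitError(
                f"smallest class has {counts.min()} members; "
                f"cannot stratify into {k} folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr.copy(), te.copy()) for tr, te in splitter.split(ds.X, y)]
    if scheme == "holdout":
        if counts.min() < 2:
            raise SplitError("each class needs >= 2 members for a holdout split")
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=fraction, random_state=seed
        )
        tr, te = next(splitter.split(ds.X, y))
        return tr.copy(), te.copy()
    raise ValueError(f"unknown scheme {scheme!r}; expected 'holdout' or 'kfold'")
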