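"""Adaptive synthetic (ADASYN) oversampling of the minority class.

ADASYN rebalances a two-class dataset by generating synthetic minority
points, allocating more of them to minority samples that are hard to
learn — those whose k nearest neighbours (over both classes, Euclidean
distance) are mostly majority points.  Each synthetic point is a convex
combination ``x_i + lam * (x_z - x_i)`` of a minority sample and one of
its minority neighbours, with ``lam`` uniform on [0, 1].

All randomness is seeded; neighbour-distance ties break by row index and
the integer allocation uses largest-remainder rounding, so identical
inputs yield identical outputs.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .schema import Dataset

logger = logging.getLogger(__name__)


def _k_nearest(dist_row: np.ndarray, k: int, exclude: int | None = None
               ) -> np.ndarray:
    """Indices of the k smallest distances; ties broken by index."""
    d = dist_row.copy()
    if exclude is not None:
        d[exclude] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:k]


def largest_remainder_allocation(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer shares of ``total`` proportional to ``weights`` (which sum
    to 1), rounding by largest remainder; allocation sums to ``total``
    exactly and ties go to the lower index."""
    shares = weights * total
    alloc = np.floor(shares).astype(int)
    short = total - alloc.sum()
    if short > 0:
        remainders = shares - alloc
        order = np.lexsort((np.arange(len(weights)), -remainders))
        alloc[order[:short]] += 1
    return alloc


class AdasynOversampler(BaseEstimator):
    """ADASYN resampler with an imbalanced-learn style ``fit_resample``.

    Parameters
    ----------
    k_neighbors : int, default 5
        Neighbourhood size for both the difficulty estimate and donor
        selection.
    beta : float, default 1.0
        Desired balance level; 1 equalises the class counts, 0 generates
        nothing.
    seed : int, default 0

    Attributes
    ----------
    minority_indices_ : row indices of the minority samples
    difficulty_ : per minority sample, the majority share of its
        neighbourhood (r_i before normalisation)
    allocation_ : integer synthetic count g_i granted to each minority
        sample (sums to ``n_synthetic_`` exactly)
    """

    def __init__(self, k_neighbors: int = 5, beta: float = 1.0, seed: int = 0):
        self.k_neighbors = k_neighbors
        self.beta = beta
        self.seed = seed

    def fit_resample(self, X: np.ndarray, y: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Append synthetic minority rows; originals pass through untouched.

        ``y`` may hold any two label values; the rarer one is the minority.
        Returns ``(X_out, y_out)`` with the synthetics appended at the end.
        """
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must be in [0, 1]")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.isfinite(X).all():
            raise ValueError("X must be finite (preprocess first)")
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) != 2:
            raise ValueError(
                f"ADASYN needs exactly two classes, found {len(labels)}"
            )
        order = np.argsort(counts, kind="stable")
        minority_label = labels[order[0]]
        m_s, m_l = counts[order[0]], counts[order[1]]
        G = int(round((m_l - m_s) * self.beta))
        self.minority_label_ = minority_label
        self.n_synthetic_ = G
        if G == 0:
            self.minority_indices_ = np.flatnonzero(y == minority_label)
            self.difficulty_ = np.zeros(m_s)
            self.allocation_ = np.zeros(m_s, dtype=int)
            return X.copy(), y.copy()

        rng = np.random.default_rng(self.seed)
        min_idx = np.flatnonzero(y == minority_label)
        X_min = X[min_idx]
        is_majority = y != minority_label

        # difficulty r_i: majority share of the k nearest neighbours in the
        # full dataset (self excluded)
        k = min(self.k_neighbors, len(X) - 1)
        d_full = np.linalg.norm(X[min_idx][:, None, :] - X[None, :, :], axis=2)
        r = np.empty(len(min_idx))
        for i, gi in enumerate(min_idx):
            nn = _k_nearest(d_full[i], k, exclude=gi)
            r[i] = is_majority[nn].mean()
        if r.sum() == 0:
            logger.info(
                "no minority point has majority neighbours; "
                "falling back to uniform allocation"
            )
            r_hat = np.full(len(min_idx), 1.0 / len(min_idx))
        else:
            r_hat = r / r.sum()
        g = largest_remainder_allocation(r_hat, G)
        self.minority_indices_ = min_idx
        self.difficulty_ = r
        self.allocation_ = g

        # minority-only neighbourhoods for donor selection
        k_min = min(self.k_neighbors, len(min_idx) - 1)
        d_min = np.linalg.norm(
            X_min[:, None, :] - X_min[None, :, :], axis=2
        )
        synth = []
        for i in range(len(min_idx)):
            if g[i] == 0:
                continue
            if k_min >= 1:
                donors = _k_nearest(d_min[i], k_min, exclude=i)
            else:
                donors = np.array([i])  # lone minority point: duplicate it
            for _ in range(int(g[i])):
                z = donors[rng.integers(len(donors))]
                lam = rng.uniform()
                synth.append(X_min[i] + lam * (X_min[z] - X_min[i]))
        X_out = np.vstack([X, np.asarray(synth)])
        y_out = np.concatenate([y, np.full(G, minority_label, dtype=y.dtype)])
        return X_out, y_out


def adasyn_oversample(
    ds: Dataset, k_neighbors: int = 5, beta: float = 1.0, seed: int = 0
) -> Dataset:
    """ADASYN on a preprocessed :class:`Dataset` (numeric, no missing)."""
    if ds.n_missing:
        raise ValueError("dataset still has missing values; preprocess first")
    X = ds.X.to_numpy(dtype=float)
    sampler = AdasynOversampler(k_neighbors=k_neighbors, beta=beta, seed=seed)
    X_out, y_out = sampler.fit_resample(X, ds.y)
    import pandas as pd

    return Dataset(
        X=pd.DataFrame(X_out, columns=ds.X.columns),
        y=y_out,
        schema=ds.schema,
        provenance=f"{ds.provenance}|adasyn(k={k_neighbors},beta={beta})",
    )
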