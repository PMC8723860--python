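"""Kernel extreme learning machine (KELM) classifier.

An extreme learning machine with an implicit feature map: instead of
random hidden weights, the Gram matrix ``Omega[i, j] = K(x_i, x_j)``
replaces ``H H^T`` and the output weights are obtained in closed form
from the ridge-regularised system

    (I / lambda + Omega) A = T,

where ``T`` is the one-hot target matrix and ``lambda > 0`` the
regularisation (normalisation) coefficient.  Prediction scores for a new
point are ``[K(x, x_1), ..., K(x, x_N)] @ A``.  The system is symmetric
positive definite for any ``lambda > 0``, so it is solved by Cholesky
factorisation — never an explicit inverse.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

KERNEL_FAMILIES = ("rbf", "linear", "polynomial")


def _kernel_matrix(
    A: np.ndarray, B: np.ndarray, family: str, gamma: float,
    degree: int, coef0: float,
) -> np.ndarray:
    if family == "rbf":
        return rbf_kernel(A, B, gamma=gamma)
    if family == "linear":
        return linear_kernel(A, B)
    if family == "polynomial":
        return polynomial_kernel(A, B, degree=degree, gamma=gamma, coef0=coef0)
    raise ValueError(f"unknown kernel family {family!r}")


class KELMClassifier(BaseEstimator, ClassifierMixin):
    """Closed-form kernel ELM classifier.

    Parameters
    ----------
    lambda_ : float, default 1.0
        Regularisation coefficient; larger values weaken the ridge term
        ``I / lambda`` and tighten the training fit.
    kernel : {"rbf", "linear", "polynomial"}, default "rbf"
    gamma : float or None
        Kernel width; ``None`` means ``1 / n_features``.
    degree, coef0 : polynomial kernel parameters.

    Attributes
    ----------
    X_train_ : (N, d) stored training matrix
    A_ : (N, C) solved coefficient matrix
    classes_ : sorted class labels
    """

    def __init__(
        self,
        lambda_: float = 1.0,
        kernel: str = "rbf",
        gamma: float | None = None,
        degree: int = 3,
        coef0: float = 1.0,
    ):
        self.lambda_ = lambda_
        self.kernel = kernel
        self.gamma = gamma
        self.degree = degree
        self.coef0 = coef0

    def _gamma_value(self, d: int) -> float:
        return 1.0 / d if self.gamma is None else float(self.gamma)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KELMClassifier":
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if self.kernel not in KERNEL_FAMILIES:
            raise ValueError(f"kernel must be one of {KERNEL_FAMILIES}")
        X, y = check_X_y(X, y)
        self.classes_ = unique_labels(y)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        g = self._gamma_value(X.shape[1])
        omega = _kernel_matrix(X, X, self.kernel, g, self.degree, self.coef0)
        if not np.isfinite(omega).all():
            raise ValueError("kernel matrix contains non-finite values")
        system = omega + np.eye(len(X)) / self.lambda_
        # positive definite for lambda_ > 0: Cholesky succeeds or raises
        factor = cho_factor(system, lower=True)
        self.A_ = cho_solve(factor, T)
        self.X_train_ = X
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores ``K(X, X_train) @ A`` (the KELM feature vector)."""
        check_is_fitted(self, "A_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects "
                f"{self.n_features_in_}"
            )
        g = self._gamma_value(self.n_features_in_)
        K = _kernel_matrix(X, self.X_train_, self.kernel, g,
                           self.degree, self.coef0)
        return K @ self.A_

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]  # ties -> lower index

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Scores clipped to [0, 1] and renormalised into a posterior.

        KELM scores approximate one-hot targets, so after clipping they
        behave like unnormalised class memberships; rows summing to zero
        fall back to uniform.
        """
        s = np.clip(self.decision_function(X), 0.0, None)
        total = s.sum(axis=1, keepdims=True)
        uniform = np.full_like(s, 1.0 / s.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, s / np.where(total > 0, total, 1.0), uniform)
        return p

    def feature_vector(self, X: np.ndarray) -> np.ndarray:
        """Per-row class-score vectors contributed to ensemble fusion."""
        return self.decision_function(np.atleast_2d(X))

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "A_")
        header = json.dumps(
            {"lambda_": self.lambda_, "kernel": self.kernel,
             "gamma": self.gamma, "degree": self.degree, "coef0": self.coef0}
        )
        np.savez(
            path, X_train=self.X_train_, A=self.A_,
            classes=self.classes_.astype(str), header=np.array(header),
        )

    @classmethod
    def load(cls, path: str | Path) -> "KELMClassifier":
        with np.load(f"{path}" if str(path).endswith(".npz") else f"{path}.npz",
                     allow_pickle=False) as z:
            params = json.loads(str(z["header"]))
            model = cls(**params)
            model.X_train_ = z["X_train"]
            model.A_ = z["A"]
            model.classes_ = z["classes"]
            model.n_features_in_ = model.X_train_.shape[1]
        return model


def train_kelm(X, y, lambda_: float = 1.0, kernel: str = "rbf",
               **kwargs) -> KELMClassifier:
    """Functional wrapper over :class:`KELMClassifier`."""
    return KELMClassifier(lambda_=lambda_, kernel=kernel, **kwargs).fit(X, y)


def predict_kelm(model: KELMClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Return (per-class scores, predicted labels)."""
    scores = model.decision_function(X)
    return scores, model.classes_[np.argmax(scores, axis=1)]


def kelm_feature_vector(model: KELMClassifier, x) -> np.ndarray:
    """Class-score vector for a single row (the fusion contribution)."""
    return model.decision_function(np.atleast_2d(x))[0]
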