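"""Deep belief network: stacked restricted Boltzmann machines.

An RBM is a bipartite energy model over binary visible units ``v`` and
hidden units ``h``:

    E(v, h) = - sum_i a_i v_i - sum_j b_j h_j - sum_ij v_i w_ij h_j

with joint probability ``P(v, h) = exp(-E) / Z``.  Conditionals factorise:
``P(h_j = 1 | v) = sigmoid(b_j + sum_i w_ij v_i)`` and symmetrically for
the visibles.  Stacked RBMs are pretrained greedily by contrastive
divergence (CD-k), each layer on the previous layer's hidden
probabilities; a softmax head is then attached and the whole stack is
fine-tuned by backpropagation on the labels.

Inputs must lie in [0, 1]: min–max scaled features are treated as
Bernoulli visible probabilities (no Gaussian-visible variant).
Probabilities, not samples, propagate between layers — lower variance at
the cost of a slight model mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as sigmoid
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


@dataclass
class RBMParams:
    """Weights ``w`` (n_v x n_h), visible biases ``a``, hidden biases ``b``."""

    w: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.w.shape != (self.a.size, self.b.size):
            raise ValueError(
                f"w has shape {self.w.shape}, expected "
                f"({self.a.size}, {self.b.size})"
            )
        if not (np.isfinite(self.w).all() and np.isfinite(self.a).all()
                and np.isfinite(self.b).all()):
            raise ValueError("RBM parameters must be finite")

    def copy(self) -> "RBMParams":
        return RBMParams(self.w.copy(), self.a.copy(), self.b.copy())


def rbm_energy(v: np.ndarray, h: np.ndarray, p: RBMParams) -> float:
    """Energy E(v, h) of a joint visible/hidden configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (p.a.size,) or h.shape != (p.b.size,):
        raise ValueError("v/h lengths do not match RBM shapes")
    return float(-(p.a @ v) - (p.b @ h) - v @ p.w @ h)


def rbm_hidden_given_visible(v: np.ndarray, p: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v) for each hidden unit; accepts a row or a batch."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != p.a.size:
        raise ValueError("visible length mismatch")
    return sigmoid(p.b + v @ p.w)


def rbm_visible_given_hidden(h: np.ndarray, p: RBMParams) -> np.ndarray:
    """P(v_i = 1 | h) for each visible unit; accepts a row or a batch."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != p.b.size:
        raise ValueError("hidden length mismatch")
    return sigmoid(p.a + h @ p.w.T)


def cd_update(
    p: RBMParams,
    batch: np.ndarray,
    lr: float = 0.1,
    cd_steps: int = 1,
    rng: np.random.Generator | None = None,
) -> RBMParams:
    """One CD-k gradient step on a batch of visible rows in [0, 1].

    Positive statistics come from the data; negative statistics from k
    alternating Gibbs half-steps (hidden units sampled, visible units kept
    as probabilities).  Returns updated parameters (input untouched).
    """
    if cd_steps < 1:
        raise ValueError("cd_steps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    v0 = np.atleast_2d(np.asarray(batch, dtype=float))
    n = len(v0)
    ph0 = rbm_hidden_given_visible(v0, p)
    h = (rng.random(ph0.shape) < ph0).astype(float)
    vk, phk = v0, ph0
    for _ in range(cd_steps):
        vk = rbm_visible_given_hidden(h, p)
        phk = rbm_hidden_given_visible(vk, p)
        h = (rng.random(phk.shape) < phk).astype(float)
    dw = (v0.T @ ph0 - vk.T @ phk) / n
    da = (v0 - vk).mean(axis=0)
    db = (ph0 - phk).mean(axis=0)
    return RBMParams(p.w + lr * dw, p.a + lr * da, p.b + lr * db)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class DBNClassifier(BaseEstimator, ClassifierMixin):
    """Stacked-RBM classifier with CD pretraining and BP fine-tuning.

    Parameters
    ----------
    hidden_sizes : tuple of int, default (32, 16)
        Hidden layer widths h_1, ..., h_L (tunable hyperparameters).
    cd_steps : int, default 1
    lr_pretrain, lr_finetune : float
        SGD learning rates for CD pretraining and supervised fine-tuning.
    epochs_pretrain, epochs_finetune : int
        ``epochs_finetune=0`` still trains the softmax head on the frozen
        pretrained features (``epochs_head`` passes, head-only).
    batch_size : int
    seed : int

    Attributes
    ----------
    layers_ : list of RBMParams
    head_w_, head_b_ : softmax output layer on the top hidden units
    pretrain_errors_ : per-layer list of per-epoch reconstruction errors
    finetune_losses_ : per-epoch mean cross-entropy
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, ...] = (32, 16),
        cd_steps: int = 1,
        lr_pretrain: float = 0.1,
        lr_finetune: float = 0.1,
        epochs_pretrain: int = 15,
        epochs_finetune: int = 30,
        epochs_head: int = 50,
        batch_size: int = 16,
        seed: int = 0,
    ):
        self.hidden_sizes = hidden_sizes
        self.cd_steps = cd_steps
        self.lr_pretrain = lr_pretrain
        self.lr_finetune = lr_finetune
        self.epochs_pretrain = epochs_pretrain
        self.epochs_finetune = epochs_finetune
        self.epochs_head = epochs_head
        self.batch_size = batch_size
        self.seed = seed

    # -- forward helpers -------------------------------------------------
    def _hidden_stack(self, X: np.ndarray) -> list[np.ndarray]:
        """Per-layer hidden probabilities, bottom to top."""
        acts = []
        cur = X
        for p in self.layers_:
            cur = rbm_hidden_given_visible(cur, p)
            acts.append(cur)
        return acts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DBNClassifier":
        X, y = check_X_y(X, y)
        if X.min() < -1e-9 or X.max() > 1 + 1e-9:
            raise ValueError("DBN inputs must lie in [0, 1]; preprocess first")
        for name in ("lr_pretrain", "lr_finetune"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        rng = np.random.default_rng(self.seed)
        self.classes_ = unique_labels(y)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        n, d = X.shape
        C = len(self.classes_)

        # greedy CD pretraining
        self.layers_ = []
        self.pretrain_errors_ = []
        cur = X
        sizes = [d, *self.hidden_sizes]
        for n_v, n_h in zip(sizes[:-1], sizes[1:]):
            p = RBMParams(
                w=rng.normal(0, 0.1, size=(n_v, n_h)),
                a=np.zeros(n_v), b=np.zeros(n_h),
            )
            errs = []
            for _ in range(self.epochs_pretrain):
                order = rng.permutation(len(cur))
                for start in range(0, len(cur), self.batch_size):
                    batch = cur[order[start:start + self.batch_size]]
                    p = cd_update(p, batch, lr=self.lr_pretrain,
                                  cd_steps=self.cd_steps, rng=rng)
                recon = rbm_visible_given_hidden(
                    rbm_hidden_given_visible(cur, p), p
                )
                errs.append(float(np.mean((cur - recon) ** 2)))
            self.layers_.append(p)
            self.pretrain_errors_.append(errs)
            cur = rbm_hidden_given_visible(cur, p)

        # softmax head on frozen top features
        top = cur
        h_L = top.shape[1]
        self.head_w_ = rng.normal(0, 0.01, size=(h_L, C))
        self.head_b_ = np.zeros(C)
        for _ in range(self.epochs_head):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                probs = _softmax(top[idx] @ self.head_w_ + self.head_b_)
                delta = (probs - T[idx]) / len(idx)
                self.head_w_ -= self.lr_finetune * top[idx].T @ delta
                self.head_b_ -= self.lr_finetune * delta.sum(axis=0)

        # joint fine-tuning by backprop (cross-entropy, plain SGD)
        self.finetune_losses_ = []
        for _ in range(self.epochs_finetune):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                self._bp_step(X[idx], T[idx])
            probs = self.predict_proba(X)
            loss = -np.mean(np.log(np.sum(probs * T, axis=1) + 1e-12))
            self.finetune_losses_.append(float(loss))
        self.n_features_in_ = d
        return self

    def _bp_step(self, Xb: np.ndarray, Tb: np.ndarray) -> None:
        acts = self._hidden_stack(Xb)
        top = acts[-1]
        probs = _softmax(top @ self.head_w_ + self.head_b_)
        m = len(Xb)
        delta = (probs - Tb) / m
        grad_hw = top.T @ delta
        grad_hb = delta.sum(axis=0)
        grad = delta @ self.head_w_.T  # dL/d(top activation)
        inputs = [Xb, *acts[:-1]]
        updates = []
        for p, inp, act in zip(reversed(self.layers_),
                               reversed(inputs), reversed(acts)):
            dz = grad * act * (1 - act)
            updates.append((p, inp.T @ dz, dz.sum(axis=0)))
            grad = dz @ p.w.T
        lr = self.lr_finetune
        for p, gw, gb in updates:
            p.w -= lr * gw
            p.b -= lr * gb
        self.head_w_ -= lr * grad_hw
        self.head_b_ -= lr * grad_hb

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "layers_")
        X = check_array(X)
        top = self._hidden_stack(X)[-1]
        return _softmax(top @ self.head_w_ + self.head_b_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def feature_vector(self, X: np.ndarray) -> np.ndarray:
        """Fusion contribution: top hidden probabilities ++ head posterior
        (length h_L + C) per row."""
        check_is_fitted(self, "layers_")
        X = check_array(np.atleast_2d(X))
        top = self._hidden_stack(X)[-1]
        probs = _softmax(top @ self.head_w_ + self.head_b_)
        return np.hstack([top, probs])


    def training_log(self):
        """Per-epoch pretraining reconstruction errors and fine-tuning
        losses as a tidy DataFrame (writable straight to CSV)."""
        import pandas as pd

        check_is_fitted(self, "layers_")
        rows = []
        for layer, errs in enumerate(self.pretrain_errors_):
            for epoch, e in enumerate(errs):
                rows.append({"phase": f"pretrain_layer{layer}",
                             "epoch": epoch, "value": e})
        for epoch, loss in enumerate(self.finetune_losses_):
            rows.append({"phase": "finetune", "epoch": epoch, "value": loss})
        return pd.DataFrame(rows, columns=["phase", "epoch", "value"])

    def save(self, path) -> None:
        import json

        check_is_fitted(self, "layers_")
        arrays = {"head_w": self.head_w_, "head_b": self.head_b_,
                  "classes": self.classes_.astype(str)}
        for i, p in enumerate(self.layers_):
            arrays[f"w{i}"], arrays[f"a{i}"], arrays[f"b{i}"] = p.w, p.a, p.b
        header = json.dumps({"params": self.get_params(),
                             "n_layers": len(self.layers_)})
        np.savez(path, header=np.array(header), **arrays)

    @classmethod
    def load(cls, path) -> "DBNClassifier":
        import json

        with np.load(str(path) if str(path).endswith(".npz")
                     else f"{path}.npz", allow_pickle=False) as z:
            meta = json.loads(str(z["header"]))
            params = meta["params"]
            params["hidden_sizes"] = tuple(params["hidden_sizes"])
            model = cls(**params)
            model.layers_ = [
                RBMParams(z[f"w{i}"], z[f"a{i}"], z[f"b{i}"])
                for i in range(meta["n_layers"])
            ]
            model.head_w_ = z["head_w"]
            model.head_b_ = z["head_b"]
            model.classes_ = z["classes"]
            model.n_features_in_ = model.layers_[0].a.size
        return model


def train_dbn(X, y, hidden_sizes=(32, 16), **kwargs) -> DBNClassifier:
    """Functional wrapper over :class:`DBNClassifier`."""
    return DBNClassifier(hidden_sizes=hidden_sizes, **kwargs).fit(X, y)


def dbn_feature_vector(model: DBNClassifier, x) -> np.ndarray:
    """Fusion vector for one row."""
    return model.feature_vector(np.atleast_2d(x))[0]
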