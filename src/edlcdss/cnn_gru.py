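"""Hybrid 1-D CNN + GRU classifier.

The feature extractor applies valid (no-padding) 1-D cross-correlations
with sigmoid activation,

    o_j = sigmoid( sum_i a_i * k_ij + b_j ),

followed by non-overlapping average pooling of width ``pool_width``
(trailing remainder discarded).  The pooled feature maps are distributed
round-robin over a bank of GRU networks; each unit's maps are flattened,
chunked into ``gru_input_size`` slices (zero-padded final chunk) and
consumed stepwise by its GRU:

    z_t = sigmoid(W_z [h_{t-1}, x_t])          update gate
    r_t = sigmoid(W_r [h_{t-1}, x_t])          reset gate
    c_t = tanh(W [r_t * h_{t-1}, x_t])         candidate state
    h_t = (1 - z_t) * h_{t-1} + z_t * c_t

Each unit's final hidden state passes through a tanh penultimate layer of
``gru_output_size`` neurons and a class softmax; the bank's posteriors
are combined by mean (a soft per-unit vote).  The concatenated
penultimate activations form the model's fusion feature vector.

Training is plain mini-batch SGD on the cross-entropy, with gradients
derived analytically throughout (no autodiff dependency); a
finite-difference check in the test suite guards the derivation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit as sigmoid
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y


# ---------------------------------------------------------------------------
# stateless building blocks
# ---------------------------------------------------------------------------

def conv1d_forward(
    a_prev: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    apply_sigmoid: bool = True,
) -> np.ndarray:
    """Valid 1-D cross-correlation over a stack of feature maps.

    Parameters
    ----------
    a_prev : (M_in, L) or (n, M_in, L)
        Input feature maps (optionally batched).
    kernels : (M_in, M_out, k)
    biases : (M_out,)

    Returns
    -------
    (…, M_out, L - k + 1) maps, sigmoid-activated unless disabled.
    """
    a = np.asarray(a_prev, dtype=float)
    squeeze = a.ndim == 2
    if squeeze:
        a = a[None]
    k = kernels.shape[2]
    if a.shape[2] < k:
        raise ValueError(
            f"input length {a.shape[2]} shorter than kernel width {k}"
        )
    windows = sliding_window_view(a, k, axis=2)  # (n, M_in, T, k)
    out = np.einsum("nitw,ijw->njt", windows, kernels) + biases[None, :, None]
    if apply_sigmoid:
        out = sigmoid(out)
    return out[0] if squeeze else out


def avg_pool(a: np.ndarray, pool_width: int = 2) -> np.ndarray:
    """Non-overlapping mean pooling along the last axis.

    A trailing remainder shorter than ``pool_width`` is discarded (the
    standard truncation rule for lengths not divisible by the width).
    """
    a = np.asarray(a, dtype=float)
    L = a.shape[-1]
    T = L // pool_width
    if T == 0:
        raise ValueError(f"map length {L} shorter than pool width {pool_width}")
    trimmed = a[..., : T * pool_width]
    return trimmed.reshape(*a.shape[:-1], T, pool_width).mean(axis=-1)


def gru_step(
    h_prev: np.ndarray,
    x: np.ndarray,
    W_z: np.ndarray,
    W_r: np.ndarray,
    W: np.ndarray,
) -> np.ndarray:
    """One GRU transition; weight matrices act on ``[h_prev, x]``."""
    h_prev = np.asarray(h_prev, dtype=float)
    x = np.asarray(x, dtype=float)
    hx = np.concatenate([h_prev, x], axis=-1)
    z = sigmoid(hx @ W_z.T)
    r = sigmoid(hx @ W_r.T)
    cand = np.tanh(np.concatenate([r * h_prev, x], axis=-1) @ W.T)
    return (1.0 - z) * h_prev + z * cand


def softmax_output(h: np.ndarray, w_k: np.ndarray) -> np.ndarray:
    """Class probabilities ``softmax(w_k @ h)``; shift-invariant in logits."""
    logits = np.asarray(h, dtype=float) @ np.asarray(w_k, dtype=float).T
    logits = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

class CNNGRUClassifier(BaseEstimator, ClassifierMixin):
    """CNN feature extractor + GRU bank classifier.

    Parameters
    ----------
    conv_layers : tuple of (n_kernels, kernel_width), default ((12, 5),)
        Stacked convolution layers; each is followed by average pooling.
    pool_width : int, default 2
    gru_input_size : int, default 25
        Slice width fed to the GRU per time step.
    gru_hidden_size : int, default 50
    gru_output_size : int, default 10
        Width of the tanh penultimate layer per GRU unit.
    n_gru_units : int, default 12
        Size of the GRU bank; capped at the number of feature maps.
    lr, epochs, batch_size, seed : SGD settings.
    """

    def __init__(
        self,
        conv_layers: tuple[tuple[int, int], ...] = ((12, 5),),
        pool_width: int = 2,
        gru_input_size: int = 25,
        gru_hidden_size: int = 50,
        gru_output_size: int = 10,
        n_gru_units: int = 12,
        lr: float = 0.5,
        epochs: int = 40,
        batch_size: int = 16,
        seed: int = 0,
    ):
        self.conv_layers = conv_layers
        self.pool_width = pool_width
        self.gru_input_size = gru_input_size
        self.gru_hidden_size = gru_hidden_size
        self.gru_output_size = gru_output_size
        self.n_gru_units = n_gru_units
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # -- initialisation --------------------------------------------------
    def _init_params(self, d: int, C: int, rng: np.random.Generator) -> None:
        self.conv_kernels_ = []
        self.conv_biases_ = []
        m_in, length = 1, d
        for n_k, width in self.conv_layers:
            if length < width:
                raise ValueError(
                    f"feature length {length} shorter than kernel width {width}"
                )
            scale = 1.0 / np.sqrt(m_in * width)
            self.conv_kernels_.append(
                rng.normal(0, scale, size=(m_in, n_k, width))
            )
            self.conv_biases_.append(np.zeros(n_k))
            length = (length - width + 1) // self.pool_width
            if length == 0:
                raise ValueError("pooling consumed the whole feature map")
            m_in = n_k
        self.n_maps_ = m_in
        self.map_len_ = length
        U = max(1, min(self.n_gru_units, self.n_maps_))
        self.n_units_ = U
        H, I, O = self.gru_hidden_size, self.gru_input_size, self.gru_output_size
        s = 1.0 / np.sqrt(H + I)
        self.W_z_ = rng.normal(0, s, size=(U, H, H + I))
        self.W_r_ = rng.normal(0, s, size=(U, H, H + I))
        self.W_ = rng.normal(0, s, size=(U, H, H + I))
        self.W_out_ = rng.normal(0, 1.0 / np.sqrt(H), size=(U, O, H))
        self.b_out_ = np.zeros((U, O))
        self.W_cls_ = rng.normal(0, 1.0 / np.sqrt(O), size=(U, C, O))
        self.b_cls_ = np.zeros((U, C))

    def _unit_slices(self) -> list[np.ndarray]:
        """Map indices owned by each GRU unit (round-robin)."""
        return [np.arange(u, self.n_maps_, self.n_units_)
                for u in range(self.n_units_)]

    # -- forward ---------------------------------------------------------
    def _forward(self, X: np.ndarray, want_cache: bool = False):
        n = len(X)
        a = X[:, None, :]  # (n, 1, d)
        conv_cache = []
        for K, b in zip(self.conv_kernels_, self.conv_biases_):
            act = conv1d_forward(a, K, b)
            pooled = avg_pool(act, self.pool_width)
            conv_cache.append((a, act))
            a = pooled
        maps = a  # (n, n_maps_, map_len_)
        I, H = self.gru_input_size, self.gru_hidden_size
        unit_cache = []
        posts = np.zeros((n, self.n_units_, self.b_cls_.shape[1]))
        penult = np.zeros((n, self.n_units_, self.gru_output_size))
        for u, midx in enumerate(self._unit_slices()):
            flat = maps[:, midx, :].reshape(n, -1)
            L = flat.shape[1]
            T = max(1, int(np.ceil(L / I)))
            seq = np.zeros((n, T, I))
            seq.reshape(n, -1)[:, :L] = flat
            h = np.zeros((n, H))
            steps = []
            for t in range(T):
                x_t = seq[:, t, :]
                hx = np.concatenate([h, x_t], axis=1)
                z = sigmoid(hx @ self.W_z_[u].T)
                r = sigmoid(hx @ self.W_r_[u].T)
                rhx = np.concatenate([r * h, x_t], axis=1)
                cand = np.tanh(rhx @ self.W_[u].T)
                h_new = (1 - z) * h + z * cand
                steps.append((h, x_t, z, r, cand))
                h = h_new
            s_o = h @ self.W_out_[u].T + self.b_out_[u]
            o = np.tanh(s_o)
            logits = o @ self.W_cls_[u].T + self.b_cls_[u]
            p = _softmax(logits)
            posts[:, u, :] = p
            penult[:, u, :] = o
            unit_cache.append((seq, steps, h, o, p, L, T))
        p_mean = posts.mean(axis=1)
        if want_cache:
            return p_mean, penult, (conv_cache, maps, unit_cache)
        return p_mean, penult

    # -- backward --------------------------------------------------------
    def _gradients(self, Xb: np.ndarray, Tb: np.ndarray
                   ) -> tuple[float, dict]:
        """Cross-entropy loss and analytic parameter gradients on a batch."""
        n = len(Xb)
        p_mean, _, (conv_cache, maps, unit_cache) = self._forward(
            Xb, want_cache=True
        )
        loss = -np.mean(np.log(np.sum(p_mean * Tb, axis=1) + 1e-12))
        dpm = -(Tb / (p_mean + 1e-12)) / n  # dL/dp_mean
        d_maps = np.zeros_like(maps)
        I, H = self.gru_input_size, self.gru_hidden_size
        grads = {
            "W_z_": np.zeros_like(self.W_z_),
            "W_r_": np.zeros_like(self.W_r_),
            "W_": np.zeros_like(self.W_),
            "W_out_": np.zeros_like(self.W_out_),
            "b_out_": np.zeros_like(self.b_out_),
            "W_cls_": np.zeros_like(self.W_cls_),
            "b_cls_": np.zeros_like(self.b_cls_),
            "conv_kernels_": [np.zeros_like(K) for K in self.conv_kernels_],
            "conv_biases_": [np.zeros_like(b) for b in self.conv_biases_],
        }
        for u, midx in enumerate(self._unit_slices()):
            seq, steps, h_T, o, p, L, T = unit_cache[u]
            g = dpm / self.n_units_  # dL/dp_u
            dlogits = p * (g - np.sum(p * g, axis=1, keepdims=True))
            dWcls = np.einsum("nc,no->co", dlogits, o)
            dbcls = dlogits.sum(axis=0)
            do = dlogits @ self.W_cls_[u]
            ds_o = do * (1 - o ** 2)
            dWout = np.einsum("no,nh->oh", ds_o, h_T)
            dbout = ds_o.sum(axis=0)
            dh = ds_o @ self.W_out_[u]
            dWz = np.zeros_like(self.W_z_[u])
            dWr = np.zeros_like(self.W_r_[u])
            dW = np.zeros_like(self.W_[u])
            dseq = np.zeros_like(seq)
            for t in range(T - 1, -1, -1):
                h_prev, x_t, z, r, cand = steps[t]
                dz = dh * (cand - h_prev)
                dcand = dh * z
                dh_prev = dh * (1 - z)
                ds = dcand * (1 - cand ** 2)
                rhx = np.concatenate([r * h_prev, x_t], axis=1)
                dW += np.einsum("nh,ni->hi", ds, rhx)
                drh = ds @ self.W_[u][:, :H]
                dx = ds @ self.W_[u][:, H:]
                dr = drh * h_prev
                dh_prev = dh_prev + drh * r
                hx = np.concatenate([h_prev, x_t], axis=1)
                duz = dz * z * (1 - z)
                dWz += np.einsum("nh,ni->hi", duz, hx)
                dh_prev = dh_prev + duz @ self.W_z_[u][:, :H]
                dx = dx + duz @ self.W_z_[u][:, H:]
                dur = dr * r * (1 - r)
                dWr += np.einsum("nh,ni->hi", dur, hx)
                dh_prev = dh_prev + dur @ self.W_r_[u][:, :H]
                dx = dx + dur @ self.W_r_[u][:, H:]
                dseq[:, t, :] = dx
                dh = dh_prev
            dflat = dseq.reshape(n, -1)[:, :L]
            d_maps[:, midx, :] += dflat.reshape(n, len(midx), self.map_len_)
            grads["W_cls_"][u] = dWcls
            grads["b_cls_"][u] = dbcls
            grads["W_out_"][u] = dWout
            grads["b_out_"][u] = dbout
            grads["W_z_"][u] = dWz
            grads["W_r_"][u] = dWr
            grads["W_"][u] = dW

        # back through conv/pool stack
        d_pooled = d_maps
        for layer in range(len(self.conv_kernels_) - 1, -1, -1):
            a_in, act = conv_cache[layer]
            K = self.conv_kernels_[layer]
            Kp = self.pool_width
            T2 = act.shape[2] // Kp
            d_act = np.zeros_like(act)
            d_act[:, :, : T2 * Kp] = np.repeat(d_pooled / Kp, Kp, axis=2)
            dZ = d_act * act * (1 - act)
            k = K.shape[2]
            windows = sliding_window_view(a_in, k, axis=2)
            dK = np.einsum("njt,nitw->ijw", dZ, windows)
            db = dZ.sum(axis=(0, 2))
            d_in = np.zeros_like(a_in)
            Tc = dZ.shape[2]
            for w in range(k):
                d_in[:, :, w:w + Tc] += np.einsum("njt,ij->nit", dZ, K[:, :, w])
            grads["conv_kernels_"][layer] = dK
            grads["conv_biases_"][layer] = db
            d_pooled = d_in
        return float(loss), grads

    def _sgd_step(self, Xb: np.ndarray, Tb: np.ndarray) -> float:
        loss, grads = self._gradients(Xb, Tb)
        lr = self.lr
        for name in ("W_z_", "W_r_", "W_", "W_out_", "b_out_",
                     "W_cls_", "b_cls_"):
            setattr(self, name, getattr(self, name) - lr * grads[name])
        self.conv_kernels_ = [K - lr * g for K, g in
                              zip(self.conv_kernels_, grads["conv_kernels_"])]
        self.conv_biases_ = [b - lr * g for b, g in
                             zip(self.conv_biases_, grads["conv_biases_"])]
        return loss

    # -- sklearn API -----------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNNGRUClassifier":
        X, y = check_X_y(X, y)
        rng = np.random.default_rng(self.seed)
        self.classes_ = unique_labels(y)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        self._init_params(X.shape[1], len(self.classes_), rng)
        self.n_features_in_ = X.shape[1]
        self.train_losses_ = []
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                epoch_loss += self._sgd_step(X[idx], T[idx]) * len(idx)
            self.train_losses_.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "conv_kernels_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature-count mismatch with the fitted model")
        p, _ = self._forward(X)
        return p

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def feature_vector(self, X: np.ndarray) -> np.ndarray:
        """Fusion contribution: concatenated per-unit penultimate
        activations (length n_units * gru_output_size) per row."""
        check_is_fitted(self, "conv_kernels_")
        X = check_array(np.atleast_2d(X))
        _, penult = self._forward(X)
        return penult.reshape(len(X), -1)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior and penultimate vector for one row."""
        p, penult = self._forward(np.atleast_2d(np.asarray(x, dtype=float)))
        return p[0], penult.reshape(1, -1)[0]


    def training_log(self):
        """Per-epoch mean cross-entropy as a DataFrame (CSV-ready)."""
        import pandas as pd

        check_is_fitted(self, "conv_kernels_")
        return pd.DataFrame({"epoch": range(len(self.train_losses_)),
                             "loss": self.train_losses_})

    def save(self, path) -> None:
        import json

        check_is_fitted(self, "conv_kernels_")
        arrays = {"W_z": self.W_z_, "W_r": self.W_r_, "W": self.W_,
                  "W_out": self.W_out_, "b_out": self.b_out_,
                  "W_cls": self.W_cls_, "b_cls": self.b_cls_,
                  "classes": self.classes_.astype(str)}
        for i, (K, b) in enumerate(zip(self.conv_kernels_,
                                       self.conv_biases_)):
            arrays[f"K{i}"], arrays[f"kb{i}"] = K, b
        header = json.dumps({"params": self.get_params(),
                             "n_conv": len(self.conv_kernels_),
                             "n_maps": self.n_maps_,
                             "map_len": self.map_len_,
                             "n_units": self.n_units_,
                             "n_features_in": self.n_features_in_})
        np.savez(path, header=np.array(header), **arrays)

    @classmethod
    def load(cls, path) -> "CNNGRUClassifier":
        import json

        with np.load(str(path) if str(path).endswith(".npz")
                     else f"{path}.npz", allow_pickle=False) as z:
            meta = json.loads(str(z["header"]))
            params = meta["params"]
            params["conv_layers"] = tuple(
                tuple(c) for c in params["conv_layers"]
            )
            model = cls(**params)
            for name, key in (("W_z_", "W_z"), ("W_r_", "W_r"), ("W_", "W"),
                              ("W_out_", "W_out"), ("b_out_", "b_out"),
                              ("W_cls_", "W_cls"), ("b_cls_", "b_cls")):
                setattr(model, name, z[key])
            model.conv_kernels_ = [z[f"K{i}"] for i in range(meta["n_conv"])]
            model.conv_biases_ = [z[f"kb{i}"] for i in range(meta["n_conv"])]
            model.classes_ = z["classes"]
            model.n_maps_ = meta["n_maps"]
            model.map_len_ = meta["map_len"]
            model.n_units_ = meta["n_units"]
            model.n_features_in_ = meta["n_features_in"]
        return model


def train_cnn_gru(X, y, **kwargs) -> CNNGRUClassifier:
    """Functional wrapper over :class:`CNNGRUClassifier`."""
    return CNNGRUClassifier(**kwargs).fit(X, y)


def cnn_gru_forward(x, model: CNNGRUClassifier):
    """Posterior and fusion vector for a single preprocessed row."""
    return model.forward(x)
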