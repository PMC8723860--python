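"""Ensemble fusion of the three classifiers and the experiment protocol.

Each trained model contributes a feature vector — KELM its class scores,
the DBN its top hidden activations plus head posterior, the CNN-GRU its
penultimate activations — and the fused representation is their exact
concatenation (length q = n + m + l).  Two decision rules are provided:

* ``soft_vote`` (default): weighted mean of the three class posteriors,
  argmax label, ties resolved to the disease class (a deliberate
  sensitivity-first clinical convention);
* ``fused_head``: a logistic head trained on the fused feature vector.

``run_experiment`` reproduces the multi-run protocol: for each run the
dataset is re-split, preprocessing is fitted on the training rows only,
ADASYN rebalances the training rows (by default — a leaky
before-the-split variant is exposed for comparison but never silently
used), the three models are trained and the held-out rows are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .adasyn import AdasynOversampler
from .cnn_gru import CNNGRUClassifier
from .dbn import DBNClassifier
from .kelm import KELMClassifier
from .metrics import MetricsReport, RunReport, compute_metrics
from .preprocess import TablePreprocessor
from .schema import Dataset
from .split import split_stratified
from .synthetic import SyntheticSpec, generate_synthetic


@dataclass(frozen=True)
class FeatureBundle:
    """Per-row fusion triple and its concatenation."""

    f_kelm: np.ndarray
    f_dbn: np.ndarray
    f_cnn_gru: np.ndarray
    fused: np.ndarray


def fuse(f_kelm: np.ndarray, f_dbn: np.ndarray, f_cnn_gru: np.ndarray
         ) -> FeatureBundle:
    """Concatenate the three model feature vectors (fixed order)."""
    parts = []
    for name, v in (("f_kelm", f_kelm), ("f_dbn", f_dbn),
                    ("f_cnn_gru", f_cnn_gru)):
        v = np.asarray(v, dtype=float).ravel()
        if v.size == 0:
            raise ValueError(f"{name} is empty; every component must "
                             "contribute features")
        parts.append(v)
    return FeatureBundle(
        f_kelm=parts[0], f_dbn=parts[1], f_cnn_gru=parts[2],
        fused=np.concatenate(parts),
    )


class EnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Three-model diagnostic ensemble.

    Parameters
    ----------
    kelm, dbn, cnn_gru : estimator instances or None
        Component classifiers (defaults constructed when None); cloned
        before fitting.
    mode : {"soft_vote", "fused_head"}
    weights : length-3 array-like or None
        Soft-vote weights (KELM, DBN, CNN-GRU order); uniform when None.
    positive_label : label treated as disease-present for tie-breaking.
    """

    def __init__(
        self,
        kelm=None,
        dbn=None,
        cnn_gru=None,
        mode: str = "soft_vote",
        weights=None,
        positive_label="ckd",
    ):
        self.kelm = kelm
        self.dbn = dbn
        self.cnn_gru = cnn_gru
        self.mode = mode
        self.weights = weights
        self.positive_label = positive_label

    def _components(self):
        return [
            self.kelm if self.kelm is not None else KELMClassifier(),
            self.dbn if self.dbn is not None else DBNClassifier(),
            self.cnn_gru if self.cnn_gru is not None else CNNGRUClassifier(),
        ]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EnsembleClassifier":
        if self.mode not in ("soft_vote", "fused_head"):
            raise ValueError("mode must be 'soft_vote' or 'fused_head'")
        self.models_ = [clone(m).fit(X, y) for m in self._components()]
        self.classes_ = self.models_[0].classes_
        if self.mode == "fused_head":
            F = self._fused_features(X)
            self.head_ = LogisticRegression(max_iter=1000).fit(F, y)
        return self

    def _fused_features(self, X: np.ndarray) -> np.ndarray:
        kelm, dbn, cnn_gru = self.models_
        return np.hstack([
            kelm.feature_vector(X),
            dbn.feature_vector(X),
            cnn_gru.feature_vector(X),
        ])

    def feature_bundle(self, x: np.ndarray) -> FeatureBundle:
        """Fusion triple for a single row."""
        kelm, dbn, cnn_gru = self.models_
        x = np.atleast_2d(x)
        return fuse(
            kelm.feature_vector(x)[0],
            dbn.feature_vector(x)[0],
            cnn_gru.feature_vector(x)[0],
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "models_")
        if self.mode == "fused_head":
            return self.head_.predict_proba(self._fused_features(X))
        w = (np.ones(3) if self.weights is None
             else np.asarray(self.weights, dtype=float))
        if w.shape != (3,) or w.sum() <= 0:
            raise ValueError("weights must be 3 non-negative values, sum > 0")
        w = w / w.sum()
        stack = np.stack([m.predict_proba(X) for m in self.models_])
        return np.einsum("m,mnc->nc", w, stack)

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        labels = self.classes_[np.argmax(p, axis=1)]
        # exact posterior ties resolve to the disease class
        if self.positive_label in self.classes_:
            pos_idx = int(np.where(self.classes_ == self.positive_label)[0][0])
            tie = np.isclose(p[:, pos_idx], p.max(axis=1), rtol=0, atol=0)
            labels = np.where(tie, self.positive_label, labels)
        return labels


def predict_ensemble(models, x, mode: str = "soft_vote", weights=None,
                     positive_label="ckd"):
    """One-row prediction from three already-trained models.

    Returns ``(label, posterior)``; ``models`` is the (kelm, dbn, cnn_gru)
    triple.
    """
    ens = EnsembleClassifier(mode=mode, weights=weights,
                             positive_label=positive_label)
    ens.models_ = list(models)
    for m in ens.models_:
        if not hasattr(m, "classes_"):
            raise ValueError("all three models must be trained first")
    ens.classes_ = ens.models_[0].classes_
    x = np.atleast_2d(x)
    return ens.predict(x)[0], ens.predict_proba(x)[0]


# ---------------------------------------------------------------------------
# experiment protocol
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Settings for the multi-run evaluation protocol.

    ``data`` is either a :class:`SyntheticSpec` or a file path readable by
    :func:`edlcdss.io.read_table`.  All randomness flows from
    ``base_seed``: run ``r`` uses ``base_seed + r`` for its split, ADASYN
    draws and model training.
    """

    data: SyntheticSpec | str = field(default_factory=SyntheticSpec)
    n_runs: int = 5
    base_seed: int = 0
    holdout_fraction: float = 0.25
    adasyn_k: int = 5
    adasyn_beta: float = 1.0
    adasyn_position: str = "after_split"  # after_split | before_split | off
    mode: str = "soft_vote"
    weights: tuple | None = None
    kelm_params: dict = field(default_factory=dict)
    dbn_params: dict = field(default_factory=dict)
    cnn_gru_params: dict = field(default_factory=dict)
    tune: tuple[str, ...] = ()
    tune_pop_size: int = 4
    tune_max_iter: int = 3

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.adasyn_position not in ("after_split", "before_split", "off"):
            raise ValueError("adasyn_position must be after_split, "
                             "before_split or off")
        if self.mode not in ("soft_vote", "fused_head"):
            raise ValueError("mode must be 'soft_vote' or 'fused_head'")
        unknown = set(self.tune) - {"dbn", "cnn_gru"}
        if unknown:
            raise ValueError(f"cannot tune unknown families {sorted(unknown)}")


def _load_dataset(data) -> Dataset:
    if isinstance(data, SyntheticSpec):
        return generate_synthetic(data)
    from .io import read_table

    return read_table(data)


def run_experiment(config: ExperimentConfig, n_runs: int | None = None
                   ) -> RunReport:
    """Execute the seeded multi-run protocol and collect a RunReport."""
    config = replace(config) if n_runs is None else replace(config,
                                                            n_runs=n_runs)
    config.validate()
    ds_raw = _load_dataset(config.data)
    pos = ds_raw.schema.positive_label

    runs: list[MetricsReport] = []
    run_meta = []
    for r in range(config.n_runs):
        seed = config.base_seed + r
        if config.adasyn_position == "before_split":
            # leaky / augmented-evaluation variant: preprocessing and
            # oversampling see every row before the split
            prep = TablePreprocessor()
            full = prep.fit_transform(ds_raw)
            from .adasyn import adasyn_oversample

            full = adasyn_oversample(full, k_neighbors=config.adasyn_k,
                                     beta=config.adasyn_beta, seed=seed)
            tr_idx, te_idx = split_stratified(
                full, "holdout", fraction=config.holdout_fraction, seed=seed
            )
            train, test = full.subset(tr_idx), full.subset(te_idx)
            X_tr, y_tr = train.X.to_numpy(float), train.y
        else:
            tr_idx, te_idx = split_stratified(
                ds_raw, "holdout", fraction=config.holdout_fraction, seed=seed
            )
            prep = TablePreprocessor()
            train = prep.fit_transform(ds_raw.subset(tr_idx))
            test = prep.transform(ds_raw.subset(te_idx))
            if config.adasyn_position == "after_split":
                X_tr, y_tr = AdasynOversampler(
                    k_neighbors=config.adasyn_k, beta=config.adasyn_beta,
                    seed=seed,
                ).fit_resample(train.X.to_numpy(float), train.y)
            else:
                X_tr, y_tr = train.X.to_numpy(float), train.y
        X_te, y_te = test.X.to_numpy(float), test.y

        dbn_params = dict(config.dbn_params)
        cnn_params = dict(config.cnn_gru_params)
        if config.tune:
            from .qoboa import ButterflyOptimizer, tune_hyperparameters

            opt = ButterflyOptimizer(pop_size=config.tune_pop_size,
                                     max_iter=config.tune_max_iter, seed=seed)
            for family in config.tune:
                best, _ = tune_hyperparameters(
                    family, X_tr, y_tr, optimizer=opt, inner_seed=seed
                )
                if family == "dbn":
                    dbn_params.update(
                        hidden_sizes=(best["h1"], best["h2"]),
                        lr_pretrain=best["lr_pretrain"],
                        lr_finetune=best["lr_finetune"],
                        epochs_finetune=best["epochs"],
                    )
                else:
                    cnn_params.update(
                        conv_layers=((best["n_kernels"], 5),),
                        gru_hidden_size=best["gru_hidden"],
                        lr=best["lr"], epochs=best["epochs"],
                    )

        ens = EnsembleClassifier(
            kelm=KELMClassifier(**config.kelm_params),
            dbn=DBNClassifier(**{"seed": seed, **dbn_params}),
            cnn_gru=CNNGRUClassifier(**{"seed": seed, **cnn_params}),
            mode=config.mode,
            weights=config.weights,
            positive_label=pos,
        ).fit(X_tr, y_tr)

        y_true = (y_te == pos).astype(int)
        p = ens.predict_proba(X_te)
        pos_idx = int(np.where(ens.classes_ == pos)[0][0])
        y_pred = (ens.predict(X_te) == pos).astype(int)
        runs.append(compute_metrics(y_true, y_pred, scores=p[:, pos_idx]))
        run_meta.append({
            "seed": seed,
            "n_train": int(len(X_tr)),
            "n_test": int(len(X_te)),
            "train_idx": [int(i) for i in tr_idx],
            "test_idx": [int(i) for i in te_idx],
            "model_accuracy": {
                name: float(np.mean(m.predict(X_te) == y_te))
                for name, m in zip(("kelm", "dbn", "cnn_gru"), ens.models_)
            },
        })
    return RunReport(runs=runs, meta={
        "adasyn_position": config.adasyn_position,
        "mode": config.mode,
        "holdout_fraction": config.holdout_fraction,
        "runs": run_meta,
        "provenance": ds_raw.provenance,
    })
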