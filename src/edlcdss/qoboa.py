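"""Quasi-oppositional butterfly optimization (QOBOA).

The butterfly optimization algorithm (BOA) is a population metaheuristic
in which each candidate ("butterfly") emits a fragrance

    f = c * I ** a

with sensor modality ``c``, stimulus intensity ``I`` and absorption
exponent ``a``.  With switch probability ``p`` a butterfly moves toward
the global best (global search),

    x <- x + (alpha^2 * g_best - x) * f,

otherwise toward the difference of two random peers (local search),

    x <- x + (alpha^2 * x_j - x_k) * f,

with ``alpha`` uniform on [0, 1] per move.  Quasi-opposition-based
learning strengthens initialisation: for every initial candidate a
quasi-opposite point is drawn uniformly between the search-space midpoint
and the candidate's mirror point, and the best half of the union is kept.

Implementation choices (the source formulation leaves them open): the
stimulus intensity is the normalised fitness rank in [0, 1] (best = 1),
moves are accepted greedily (only if they improve), and the global best
is elitist.  Integer dimensions are rounded after clipping; log-scaled
dimensions are searched in log10 space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTINUOUS = "continuous"
INTEGER = "integer"
LOG = "log"


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    kind: str = CONTINUOUS

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: need low < high")
        if self.kind not in (CONTINUOUS, INTEGER, LOG):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == LOG and self.low <= 0:
            raise ValueError(f"{self.name}: log dimension needs low > 0")


@dataclass(frozen=True)
class SearchSpace:
    """Box-constrained search space; positions are handled internally in
    log10 coordinates for log dimensions."""

    dims: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(self.dims))
        if not self.dims:
            raise ValueError("search space needs at least one dimension")

    @property
    def lower(self) -> np.ndarray:
        return np.array([np.log10(d.low) if d.kind == LOG else d.low
                         for d in self.dims])

    @property
    def upper(self) -> np.ndarray:
        return np.array([np.log10(d.high) if d.kind == LOG else d.high
                         for d in self.dims])

    def clip(self, x: np.ndarray) -> np.ndarray:
        """Clip to bounds; integer dimensions rounded after clipping."""
        out = np.clip(np.asarray(x, dtype=float), self.lower, self.upper)
        for i, d in enumerate(self.dims):
            if d.kind == INTEGER:
                out[..., i] = np.rint(out[..., i])
        return out

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.uniform(self.lower, self.upper, size=(n, len(self.dims)))
        return self.clip(u)

    def decode(self, x: np.ndarray) -> dict[str, float]:
        """Internal position -> named parameter values."""
        out = {}
        for i, d in enumerate(self.dims):
            v = float(x[i])
            if d.kind == LOG:
                v = 10.0 ** v
            elif d.kind == INTEGER:
                v = int(round(v))
            out[d.name] = v
        return out


def fragrance(c: float, I: float, a: float) -> float:
    """Fragrance f = c * I**a; the stimulus intensity must be >= 0."""
    if I < 0:
        raise ValueError("stimulus intensity must be >= 0")
    return c * I ** a


def quasi_opposite(
    x: np.ndarray, space: SearchSpace, rng: np.random.Generator
) -> np.ndarray:
    """Quasi-opposite point: per dimension, uniform between the interval
    midpoint ``(lo + hi) / 2`` and the mirror point ``lo + hi - x``."""
    x = np.asarray(x, dtype=float)
    lo, hi = space.lower, space.upper
    mid = (lo + hi) / 2.0
    mirror = lo + hi - x
    a = np.minimum(mid, mirror)
    b = np.maximum(mid, mirror)
    return space.clip(rng.uniform(a, b))


def global_move(
    x: np.ndarray, g_best: np.ndarray, frag: float,
    rng: np.random.Generator, space: SearchSpace,
) -> np.ndarray:
    """Move toward the global best, scaled by fragrance."""
    alpha = rng.uniform()
    return space.clip(x + (alpha ** 2 * g_best - x) * frag)


def local_move(
    x: np.ndarray, x_j: np.ndarray, x_k: np.ndarray, frag: float,
    rng: np.random.Generator, space: SearchSpace,
) -> np.ndarray:
    """Move along the difference of two peers, scaled by fragrance."""
    alpha = rng.uniform()
    return space.clip(x + (alpha ** 2 * x_j - x_k) * frag)


@dataclass
class OptimizeResult:
    x: np.ndarray
    params: dict[str, float]
    fitness: float
    history: list[float] = field(default_factory=list)
    n_evals: int = 0


class ButterflyOptimizer:
    """QOBOA minimiser over a :class:`SearchSpace`.

    Parameters
    ----------
    pop_size : int, default 20
    max_iter : int, default 50
    c : float, default 0.01
        Sensor modality.
    a : float, default 0.1
        Power exponent of fragrance absorption.
    p : float, default 0.8
        Probability of the global-search move.
    quasi_opposition : {"init_only", "jumping"}, default "init_only"
    jumping_rate : float, default 0.1
        Per-iteration probability of a quasi-oppositional jump when
        ``quasi_opposition="jumping"``.
    seed : int
    """

    def __init__(
        self,
        pop_size: int = 20,
        max_iter: int = 50,
        c: float = 0.01,
        a: float = 0.1,
        p: float = 0.8,
        quasi_opposition: str = "init_only",
        jumping_rate: float = 0.1,
        seed: int = 0,
    ):
        if pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0 <= p <= 1:
            raise ValueError("p must be in [0, 1]")
        if not 0 < a <= 1:
            raise ValueError("a must be in (0, 1]")
        if c <= 0:
            raise ValueError("c must be > 0")
        if quasi_opposition not in ("init_only", "jumping"):
            raise ValueError("quasi_opposition must be 'init_only' or 'jumping'")
        self.pop_size = pop_size
        self.max_iter = max_iter
        self.c = c
        self.a = a
        self.p = p
        self.quasi_opposition = quasi_opposition
        self.jumping_rate = jumping_rate
        self.seed = seed

    def optimize(self, objective, space: SearchSpace) -> OptimizeResult:
        """Minimise ``objective(position_vector)`` over the space."""
        rng = np.random.default_rng(self.seed)
        n_evals = 0

        def ev(x):
            nonlocal n_evals
            n_evals += 1
            return float(objective(x))

        pop = space.sample(rng, self.pop_size)
        qpop = np.array([quasi_opposite(x, space, rng) for x in pop])
        union = np.vstack([pop, qpop])
        fits = np.array([ev(x) for x in union])
        order = np.argsort(fits, kind="stable")[: self.pop_size]
        pop, fits = union[order], fits[order]

        best_i = int(np.argmin(fits))
        g_best, g_fit = pop[best_i].copy(), float(fits[best_i])
        history = [g_fit]

        for _ in range(self.max_iter):
            # stimulus intensity from fitness rank: best = 1, worst = 1/pop
            ranks = np.argsort(np.argsort(fits, kind="stable"), kind="stable")
            intensity = (self.pop_size - ranks) / self.pop_size
            for i in range(self.pop_size):
                frag = fragrance(self.c, float(intensity[i]), self.a)
                if rng.uniform() < self.p:
                    cand = global_move(pop[i], g_best, frag, rng, space)
                else:
                    j, k = rng.choice(self.pop_size, size=2, replace=False)
                    cand = local_move(pop[i], pop[j], pop[k], frag, rng, space)
                f_cand = ev(cand)
                if f_cand < fits[i]:  # greedy acceptance
                    pop[i], fits[i] = cand, f_cand
                    if f_cand < g_fit:
                        g_best, g_fit = cand.copy(), f_cand
            if (self.quasi_opposition == "jumping"
                    and rng.uniform() < self.jumping_rate):
                qpop = np.array([quasi_opposite(x, space, rng) for x in pop])
                qfits = np.array([ev(x) for x in qpop])
                union = np.vstack([pop, qpop])
                ufits = np.concatenate([fits, qfits])
                order = np.argsort(ufits, kind="stable")[: self.pop_size]
                pop, fits = union[order], ufits[order]
                if fits[0] < g_fit:
                    g_best, g_fit = pop[0].copy(), float(fits[0])
            history.append(g_fit)

        return OptimizeResult(
            x=g_best, params=space.decode(g_best), fitness=g_fit,
            history=history, n_evals=n_evals,
        )


def optimize(objective, space: SearchSpace, **kwargs) -> OptimizeResult:
    """Functional wrapper over :class:`ButterflyOptimizer`."""
    return ButterflyOptimizer(**kwargs).optimize(objective, space)


# ---------------------------------------------------------------------------
# hyperparameter tuning for the DBN and CNN-GRU classifiers
# ---------------------------------------------------------------------------

DEFAULT_SPACES = {
    "dbn": SearchSpace((
        Dimension("h1", 8, 64, INTEGER),
        Dimension("h2", 4, 32, INTEGER),
        Dimension("lr_pretrain", 1e-3, 0.5, LOG),
        Dimension("lr_finetune", 1e-3, 0.5, LOG),
        Dimension("epochs", 5, 30, INTEGER),
    )),
    "cnn_gru": SearchSpace((
        Dimension("n_kernels", 4, 16, INTEGER),
        Dimension("gru_hidden", 8, 64, INTEGER),
        Dimension("lr", 1e-2, 1.0, LOG),
        Dimension("epochs", 5, 40, INTEGER),
    )),
}


def _build_model(family: str, params: dict, inner_seed: int):
    from .cnn_gru import CNNGRUClassifier
    from .dbn import DBNClassifier

    if family == "dbn":
        return DBNClassifier(
            hidden_sizes=(int(params["h1"]), int(params["h2"])),
            lr_pretrain=params["lr_pretrain"],
            lr_finetune=params["lr_finetune"],
            epochs_pretrain=max(1, int(params["epochs"]) // 2),
            epochs_finetune=int(params["epochs"]),
            seed=inner_seed,
        )
    if family == "cnn_gru":
        return CNNGRUClassifier(
            conv_layers=((int(params["n_kernels"]), 5),),
            gru_hidden_size=int(params["gru_hidden"]),
            lr=params["lr"],
            epochs=int(params["epochs"]),
            seed=inner_seed,
        )
    raise ValueError(f"unknown model family {family!r}")


def tune_hyperparameters(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    space: SearchSpace | None = None,
    optimizer: ButterflyOptimizer | None = None,
    holdout_fraction: float = 0.25,
    inner_seed: int = 0,
) -> tuple[dict, OptimizeResult]:
    """Search model hyperparameters by minimising 1 - validation accuracy.

    The validation split and every candidate's training seed are fixed, so
    the objective is deterministic and the search reproducible.
    """
    from sklearn.model_selection import train_test_split

    if family not in DEFAULT_SPACES:
        raise ValueError(f"unknown model family {family!r}")
    space = DEFAULT_SPACES[family] if space is None else space
    optimizer = optimizer or ButterflyOptimizer(pop_size=6, max_iter=5)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, test_size=holdout_fraction, stratify=y, random_state=inner_seed
    )

    def objective(position: np.ndarray) -> float:
        params = space.decode(position)
        model = _build_model(family, params, inner_seed)
        model.fit(X_tr, y_tr)
        acc = float(np.mean(model.predict(X_va) == y_va))
        return 1.0 - acc

    result = optimizer.optimize(objective, space)
    return result.params, result
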