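"""Improved backpropagation network (IBPNN).

A single-hidden-layer sigmoid MLP trained online (per sample) with two
departures from vanilla backpropagation:

* an *adaptive learning rate* alpha(t), updated once per epoch from the mean
  epoch error E: alpha shrinks by 1% when the error grew by more than 4%,
  grows by 1% when the error fell, and is otherwise unchanged;
* a *forgetting factor* beta, a constant scaling the previous step's gradient
  term, so each update is ``alpha * g(t) + beta * alpha * g(t-1)`` — a
  one-step momentum memory.

Forward pass: ``h_j = f(sum_i w_ij x_i - theta_j)``,
``y_k = f(sum_j w_jk h_j - theta_k)`` with the logistic f; the per-sample
error is ``E = 1/2 sum_k (y_k - yhat_k)^2``.  Note the thresholds theta enter
with a minus sign, so their gradient terms carry an explicit (-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .data import Dataset


def sigmoid(z):
    """Logistic function 1/(1+exp(-z)), numerically stable for large |z|."""
    return expit(z)


@dataclass
class NetworkParams:
    """Weights and thresholds of one network.

    ``w_hidden`` is (n, m) — input x hidden; ``w_out`` is (m, l).  The
    thresholds ``theta_hidden`` (m,) and ``theta_out`` (l,) are subtracted
    from the weighted sums before the activation.
    """

    w_hidden: np.ndarray
    theta_hidden: np.ndarray
    w_out: np.ndarray
    theta_out: np.ndarray

    def __post_init__(self) -> None:
        self.w_hidden = np.asarray(self.w_hidden, dtype=float)
        self.theta_hidden = np.asarray(self.theta_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.theta_out = np.asarray(self.theta_out, dtype=float)
        n, m = self.w_hidden.shape
        m2, l = self.w_out.shape
        if m2 != m or self.theta_hidden.shape != (m,) or self.theta_out.shape != (l,):
            raise ValueError("inconsistent parameter shapes")
        for a in (self.w_hidden, self.theta_hidden, self.w_out, self.theta_out):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite network parameter")

    @property
    def n(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def m(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def l(self) -> int:
        return self.w_out.shape[1]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.w_hidden.copy(), self.theta_hidden.copy(), self.w_out.copy(), self.theta_out.copy()
        )

    # -- flat-vector view (the ABC search space) -----------------------------

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.w_hidden.ravel(), self.theta_hidden, self.w_out.ravel(), self.theta_out]
        )

    @classmethod
    def unflatten(cls, vec: np.ndarray, n: int, m: int, l: int) -> "NetworkParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (param_count(n, m, l),):
            raise ValueError(f"expected {param_count(n, m, l)} values for ({n},{m},{l}), got {vec.shape}")
        i = 0
        w_h = vec[i : i + n * m].reshape(n, m); i += n * m
        t_h = vec[i : i + m]; i += m
        w_o = vec[i : i + m * l].reshape(m, l); i += m * l
        t_o = vec[i : i + l]
        return cls(w_h, t_h, w_o, t_o)

    # -- JSON serialization --------------------------------------------------

    def to_dict(self, meta: dict | None = None) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "l": self.l,
            "w_hidden": self.w_hidden.tolist(),
            "theta_hidden": self.theta_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "theta_out": self.theta_out.tolist(),
            "meta": meta or {},
        }

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(meta)))

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        p = cls(
            np.asarray(d["w_hidden"]), np.asarray(d["theta_hidden"]),
            np.asarray(d["w_out"]), np.asarray(d["theta_out"]),
        )
        if (p.n, p.m, p.l) != (d["n"], d["m"], d["l"]):
            raise ValueError("serialized layer sizes disagree with array shapes")
        return p

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def param_count(n: int, m: int, l: int) -> int:
    """Number of stored weights and thresholds: m(n+1) + l(m+1)."""
    return m * (n + 1) + l * (m + 1)


def init_params(n: int, m: int, l: int, init_range=(-1.0, 1.0), seed: int = 0) -> NetworkParams:
    """Uniform random initialization over ``init_range``, deterministic per seed."""
    lo, hi = init_range
    if lo >= hi:
        raise ValueError("init_range low bound must be below high bound")
    rng = np.random.default_rng(seed)
    u = lambda *shape: rng.uniform(lo, hi, size=shape)
    return NetworkParams(u(n, m), u(m), u(m, l), u(l))


# ---------------------------------------------------------------------------
# Forward / error


def forward(p: NetworkParams, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden and output activations for one input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (p.n,):
        raise ValueError(f"input length {x.shape} does not match n={p.n}")
    h = sigmoid(x @ p.w_hidden - p.theta_hidden)
    y = sigmoid(h @ p.w_out - p.theta_out)
    return h, y


def forward_batch(p: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Output activations for a (N, n) batch."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != p.n:
        raise ValueError(f"batch shape {X.shape} does not match n={p.n}")
    H = sigmoid(X @ p.w_hidden - p.theta_hidden)
    return sigmoid(H @ p.w_out - p.theta_out)


def error(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Half squared error 1/2 sum_k (y_k - yhat_k)^2."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("output and target lengths differ")
    return 0.5 * float(np.sum((y - y_hat) ** 2))


def predict(p: NetworkParams, x: np.ndarray) -> int:
    """Argmax class index; ties break toward the lowest index."""
    _, y = forward(p, x)
    return int(np.argmax(y))


def predict_batch(p: NetworkParams, X: np.ndarray) -> np.ndarray:
    return np.argmax(forward_batch(p, X), axis=1)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    """Hyperparameters of the improved trainer.

    beta is the forgetting factor (0 disables the memory term); alpha0 the
    initial learning rate; target_error an optional early stop on the mean
    epoch error.
    """

    alpha0: float = 0.05
    beta: float = 0.5
    epochs: int = 50
    seed: int = 0
    init_range: tuple[float, float] = (-1.0, 1.0)
    target_error: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.init_range[0] >= self.init_range[1]:
            raise ValueError("init_range low bound must be below high bound")


@dataclass
class TrainState:
    """Mutable per-run state: current alpha and the previous step's gradient
    terms (one slot per parameter group), zeros before the first step."""

    alpha: float
    g_w_out: np.ndarray
    g_theta_out: np.ndarray
    g_w_hidden: np.ndarray
    g_theta_hidden: np.ndarray

    @classmethod
    def initial(cls, p: NetworkParams, alpha0: float) -> "TrainState":
        return cls(
            alpha0,
            np.zeros_like(p.w_out),
            np.zeros_like(p.theta_out),
            np.zeros_like(p.w_hidden),
            np.zeros_like(p.theta_hidden),
        )


@dataclass
class TrainHistory:
    epoch_error: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epoch_error)


def update_alpha(alpha: float, curr_error: float, prev_error: float) -> float:
    """Adaptive learning-rate rule: x0.99 if the error grew by >4%, x1.01 if
    it fell, unchanged otherwise."""
    if curr_error > 1.04 * prev_error:
        return 0.99 * alpha
    if curr_error < prev_error:
        return 1.01 * alpha
    return alpha


def backprop_step(
    p: NetworkParams, x: np.ndarray, y_hat: np.ndarray, state: TrainState, beta: float
) -> float:
    """One online update from a single (x, target) pair, in place.

    All gradient terms are evaluated on the pre-update forward pass, then both
    layers' deltas are applied simultaneously:
    ``delta = alpha * g(t) + beta * alpha * g(t-1)``, with the previous step's
    terms taken from ``state`` and this step's stored back into it. Returns the
    pre-update half squared error.
    """
    h, y = forward(p, x)
    delta_out = (y_hat - y) * y * (1.0 - y)                    # (l,)
    delta_hid = h * (1.0 - h) * (p.w_out @ delta_out)          # (m,)
    g_w_out = np.outer(h, delta_out)
    g_theta_out = -delta_out
    g_w_hidden = np.outer(np.asarray(x, dtype=float), delta_hid)
    g_theta_hidden = -delta_hid

    a, b = state.alpha, beta * state.alpha
    p.w_out += a * g_w_out + b * state.g_w_out
    p.theta_out += a * g_theta_out + b * state.g_theta_out
    p.w_hidden += a * g_w_hidden + b * state.g_w_hidden
    p.theta_hidden += a * g_theta_hidden + b * state.g_theta_hidden

    state.g_w_out = g_w_out
    state.g_theta_out = g_theta_out
    state.g_w_hidden = g_w_hidden
    state.g_theta_hidden = g_theta_hidden
    return error(y, y_hat)


def train(
    p0: NetworkParams, ds: Dataset, cfg: TrainConfig
) -> tuple[NetworkParams, TrainHistory]:
    """Train online with per-epoch shuffling; alpha adapts once per epoch.

    ``ds`` must carry integer targets (``ds.y``/``ds.n_classes``) matching the
    network's output layer; they are expanded one-hot.
    """
    if len(ds) == 0:
        raise ValueError("cannot train on an empty dataset")
    T = ds.targets_onehot()
    if ds.dim != p0.n or T.shape[1] != p0.l:
        raise ValueError(
            f"dataset dims ({ds.dim} in, {T.shape[1]} classes) do not match network ({p0.n}, {p0.l})"
        )
    p = p0.copy()
    state = TrainState.initial(p, cfg.alpha0)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    prev_error = None
    for _ in range(cfg.epochs):
        order = rng.permutation(len(ds))
        errs = np.empty(len(ds))
        for j, i in enumerate(order):
            errs[j] = backprop_step(p, ds.X[i], T[i], state, cfg.beta)
        mean_err = float(errs.mean())
        history.epoch_error.append(mean_err)
        history.alpha.append(state.alpha)
        if prev_error is not None:
            state.alpha = update_alpha(state.alpha, mean_err, prev_error)
        prev_error = mean_err
        if mean_err < cfg.target_error:
            break
    return p, history
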