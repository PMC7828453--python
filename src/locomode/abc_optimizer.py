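"""Artificial bee colony (ABC) search over network initial parameters.

ABC maintains N food sources (candidate flattened weight/threshold vectors).
Each local iteration runs three phases:

* collecting (employed) bees perturb every source in one random dimension
  toward/away from a random partner and keep the candidate under a greedy
  ``>=`` rule on the transformed fitness;
* following (onlooker) bees re-sample sources proportionally to fitness and
  apply the same neighborhood move, acting on the selected source in place;
* scout bees replace any source whose stagnation counter reached ``limit``
  with a fresh uniform draw (the global best is recorded first and never lost).

The raw objective E (here the network's mean half-squared error after a short
frozen training probe) is minimized; the selection fitness is the standard
transform ``fit = 1/(1+E)``, so Eq.-style proportional selection favors low
error.  The whole schedule is repeated ``n_global`` times from fresh random
populations and the best position over all rounds is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data import Dataset
from .ibpnn import NetworkParams, TrainConfig, forward_batch, param_count, train


@dataclass
class ABCConfig:
    """Colony geometry and search schedule.

    ``colony_size`` N counts the collecting (= following) bees; ``limit`` is
    the stagnation threshold for scout replacement; ``bounds`` the per-dimension
    box (a scalar pair applies to every dimension). ``probe_epochs`` /
    ``probe_subsample`` control the fitness probe used when optimizing network
    initializations (0 probe epochs scores the raw forward error).
    """

    colony_size: int = 20
    dim: int | None = None
    bounds: tuple[float, float] = (-1.0, 1.0)
    limit: int = 50
    n_global: int = 2
    n_local: int = 50
    seed: int = 0
    probe_epochs: int = 1
    probe_subsample: int = 256

    def __post_init__(self) -> None:
        if self.colony_size < 2:
            raise ValueError("colony_size must be at least 2")
        if self.limit < 1:
            raise ValueError("limit must be at least 1")
        if self.n_global < 1 or self.n_local < 1:
            raise ValueError("n_global and n_local must be at least 1")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("lower bound must be strictly below upper bound")


@dataclass
class FoodSource:
    """One candidate position with its raw objective, transformed fitness and
    stagnation counter."""

    position: np.ndarray
    objective: float
    fitness: float
    trials: int = 0


@dataclass
class ABCTrace:
    """Best-so-far raw objective per local iteration, one array per global
    round (the convergence curves), plus the overall winner."""

    rounds: list[np.ndarray] = field(default_factory=list)
    best_position: np.ndarray | None = None
    best_objective: float = np.inf

    def to_csv(self, path: str | Path) -> None:
        lines = ["round,iteration,best_objective"]
        for r, curve in enumerate(self.rounds):
            lines += [f"{r},{i},{v!r}" for i, v in enumerate(curve)]
        Path(path).write_text("\n".join(lines) + "\n")


def fitness_from_objective(e: float) -> float:
    """Transform a minimized raw objective E >= 0 into a selection fitness."""
    return 1.0 / (1.0 + e)


def init_sources(
    fn: Callable[[np.ndarray], float], cfg: ABCConfig, rng: np.random.Generator
) -> list[FoodSource]:
    """Draw N uniform positions within bounds and evaluate them."""
    lo, hi = cfg.bounds
    sources = []
    for _ in range(cfg.colony_size):
        pos = rng.uniform(lo, hi, size=cfg.dim)
        e = fn(pos)
        sources.append(FoodSource(pos, e, fitness_from_objective(e)))
    return sources


def neighborhood_candidate(
    position: np.ndarray, partner: np.ndarray, rng: np.random.Generator, bounds: tuple[float, float]
) -> np.ndarray:
    """Perturb one random dimension toward/away from a partner source.

    ``new_j = x_j + phi * (x_j - partner_j)`` with phi uniform on [-1, 1];
    every other coordinate is copied and the result is clipped to bounds.
    """
    if position is partner or np.shares_memory(position, partner):
        raise ValueError("partner must be a different source")
    j = int(rng.integers(position.shape[0]))
    phi = rng.uniform(-1.0, 1.0)
    cand = position.copy()
    cand[j] = np.clip(cand[j] + phi * (cand[j] - partner[j]), *bounds)
    return cand


def greedy_select(
    src: FoodSource, cand_position: np.ndarray, fn: Callable[[np.ndarray], float]
) -> FoodSource:
    """Keep the candidate iff its fitness is >= the source's (ties favor the
    candidate); resets or increments the stagnation counter accordingly."""
    e = fn(cand_position)
    fit = fitness_from_objective(e)
    if fit >= src.fitness:
        return FoodSource(cand_position, e, fit, trials=0)
    src.trials += 1
    return src


def selection_probabilities(sources: Sequence[FoodSource]) -> np.ndarray:
    """Fitness-proportional following probabilities (sum to 1)."""
    fits = np.array([s.fitness for s in sources])
    if np.any(fits <= 0):
        raise ValueError("selection requires strictly positive fitness values")
    return fits / fits.sum()


def scout_phase(
    sources: list[FoodSource], fn: Callable[[np.ndarray], float], cfg: ABCConfig, rng: np.random.Generator
) -> None:
    """Replace stagnant sources (trials >= limit) with fresh uniform draws."""
    lo, hi = cfg.bounds
    for i, src in enumerate(sources):
        if src.trials >= cfg.limit:
            pos = rng.uniform(lo, hi, size=len(src.position))
            e = fn(pos)
            sources[i] = FoodSource(pos, e, fitness_from_objective(e))


def _random_partner(sources: list[FoodSource], i: int, rng: np.random.Generator) -> np.ndarray:
    k = int(rng.integers(len(sources) - 1))
    if k >= i:
        k += 1
    return sources[k].position


def optimize(fn: Callable[[np.ndarray], float], cfg: ABCConfig) -> tuple[np.ndarray, ABCTrace]:
    """Run the full n_global x n_local schedule; deterministic per cfg.seed."""
    if cfg.dim is None or cfg.dim < 1:
        raise ValueError("cfg.dim must be a positive integer")
    rng = np.random.default_rng(cfg.seed)
    trace = ABCTrace()
    for round_idx in range(cfg.n_global):
        sources = init_sources(fn, cfg, rng)
        round_best = min(s.objective for s in sources)
        curve = np.empty(cfg.n_local)
        for it in range(cfg.n_local):
            # collecting-bee phase
            for i in range(len(sources)):
                cand = neighborhood_candidate(
                    sources[i].position, _random_partner(sources, i, rng), rng, cfg.bounds
                )
                sources[i] = greedy_select(sources[i], cand, fn)
            # following-bee phase
            probs = selection_probabilities(sources)
            for _ in range(len(sources)):
                i = int(rng.choice(len(sources), p=probs))
                cand = neighborhood_candidate(
                    sources[i].position, _random_partner(sources, i, rng), rng, cfg.bounds
                )
                sources[i] = greedy_select(sources[i], cand, fn)
            # record the elite before scouting can discard it
            for s in sources:
                if s.objective < trace.best_objective:
                    trace.best_objective = s.objective
                    trace.best_position = s.position.copy()
                round_best = min(round_best, s.objective)
            curve[it] = round_best
            scout_phase(sources, fn, cfg, rng)
        trace.rounds.append(curve)
    return trace.best_position, trace


# ---------------------------------------------------------------------------
# Network-initialization objective


def network_objective(
    train_ds: Dataset, arch: tuple[int, int, int], probe: TrainConfig, cfg: ABCConfig
) -> Callable[[np.ndarray], float]:
    """Build the deterministic fitness probe for one architecture.

    A candidate position is unflattened into initial parameters, trained for
    ``cfg.probe_epochs`` epochs on a frozen subsample of the training set, and
    scored by the mean half-squared output error on that subsample. With zero
    probe epochs the raw forward error of the untrained candidate is scored.
    """
    n, m, l = arch
    rng = np.random.default_rng(probe.seed)
    take = min(cfg.probe_subsample, len(train_ds))
    idx = rng.choice(len(train_ds), size=take, replace=False)
    X = train_ds.X[idx]
    T = train_ds.targets_onehot()[idx]
    sub = Dataset(X, train_ds.labels[idx], train_ds.window_ms,
                  y=train_ds.y[idx], n_classes=train_ds.n_classes)
    probe_cfg = TrainConfig(
        alpha0=probe.alpha0, beta=probe.beta, epochs=max(cfg.probe_epochs, 1),
        seed=probe.seed, init_range=probe.init_range, target_error=0.0,
    )

    def objective(position: np.ndarray) -> float:
        p = NetworkParams.unflatten(position, n, m, l)
        if cfg.probe_epochs > 0:
            p, _ = train(p, sub, probe_cfg)
        Y = forward_batch(p, X)
        return float(0.5 * np.sum((Y - T) ** 2, axis=1).mean())

    return objective


def abc_init_network(
    train_ds: Dataset, arch: tuple[int, int, int], cfg: ABCConfig, probe: TrainConfig
) -> NetworkParams:
    """Pick initial weights/thresholds for one network by ABC search."""
    n, m, l = arch
    d = param_count(n, m, l)
    if cfg.dim is not None and cfg.dim != d:
        raise ValueError(f"cfg.dim={cfg.dim} does not match architecture dimension {d}")
    cfg = ABCConfig(**{**cfg.__dict__, "dim": d})
    best, _ = optimize(network_objective(train_ds, arch, probe, cfg), cfg)
    return NetworkParams.unflatten(best, n, m, l)
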