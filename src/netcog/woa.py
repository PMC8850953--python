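"""Whale optimization algorithm (WOA).

A population metaheuristic modelled on humpback bubble-net feeding. Each
iteration every whale either (i) shrinks an encircling move around the best
position found so far, (ii) spirals towards it, or (iii) explores towards a
randomly chosen whale. The control scalar ``a`` decays linearly from 2 to 0,
shifting the population from exploration (|A| >= 1) to exploitation
(|A| < 1); a coin flip with probability ``switch_prob`` chooses between the
encircle/explore pair and the spiral move. The incumbent best is elitist:
it only ever improves.

Used here to minimise cross-validated prediction error over LS-SVR
hyperparameters (searched in log10 space), but generic over any objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "WOAConfig",
    "WOAState",
    "WOAResult",
    "FitnessSpec",
    "init_population",
    "encircle_update",
    "spiral_update",
    "explore_update",
    "optimize",
]


@dataclass(frozen=True)
class WOAConfig:
    """Population size, iteration budget, spiral shape, box bounds, seed.

    ``warm_starts`` are positions injected into the initial population
    (e.g. a known-reasonable default), replacing random whales."""

    bounds: tuple[tuple[float, float], ...]
    n_whales: int = 30
    n_iterations: int = 100
    spiral_b: float = 1.0
    switch_prob: float = 0.5
    seed: int = 0
    warm_starts: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.n_whales < 2:
            raise ValueError("n_whales must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must lie in [0, 1]")
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        if not bounds or any(lo >= hi for lo, hi in bounds):
            raise ValueError("each bound must satisfy low < high")
        object.__setattr__(self, "bounds", bounds)

    @property
    def dim(self) -> int:
        return len(self.bounds)


@dataclass(frozen=True)
class FitnessSpec:
    """Objective to MINIMISE; non-finite values are treated as +inf."""

    objective: Callable[[np.ndarray], float]
    description: str = ""


@dataclass
class WOAState:
    """Whale positions plus the coefficients drawn for the last update."""

    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    a: float = 2.0
    A: np.ndarray = field(default_factory=lambda: np.zeros(0))
    C: np.ndarray = field(default_factory=lambda: np.zeros(0))
    q: np.ndarray = field(default_factory=lambda: np.zeros(0))
    l: float = 0.0
    p: float = 0.0
    iteration: int = 0


@dataclass
class WOAResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    state: WOAState


def _safe_eval(spec: FitnessSpec, x: np.ndarray) -> float:
    val = float(spec.objective(np.asarray(x, dtype=float)))
    return val if np.isfinite(val) else np.inf


def init_population(cfg: WOAConfig, fitness: FitnessSpec | None = None,
                    rng: np.random.Generator | None = None) -> WOAState:
    """Seeded uniform positions within bounds; best = argmin over whales."""
    rng = rng or np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    pos = rng.uniform(lo, hi, size=(cfg.n_whales, cfg.dim))
    for i, ws in enumerate(cfg.warm_starts[: cfg.n_whales]):
        pos[i] = np.clip(np.asarray(ws, dtype=float), lo, hi)
    if fitness is not None:
        fit = np.array([_safe_eval(fitness, p) for p in pos])
    else:
        fit = np.full(cfg.n_whales, np.inf)
    best = int(np.argmin(fit))
    return WOAState(
        positions=pos,
        fitness=fit,
        best_position=pos[best].copy(),
        best_fitness=float(fit[best]),
    )


def encircle_update(x: np.ndarray, x_star: np.ndarray,
                    A: np.ndarray | float, C: np.ndarray | float) -> np.ndarray:
    """Shrinking-encircling move: x* - A * |C * x* - x| (element-wise)."""
    x = np.asarray(x, float)
    x_star = np.asarray(x_star, float)
    return x_star - np.asarray(A) * np.abs(np.asarray(C) * x_star - x)


def spiral_update(x: np.ndarray, x_star: np.ndarray,
                  spiral_b: float, l: float) -> np.ndarray:
    """Logarithmic-spiral move: |x - x*| e^(b l) cos(2 pi l) + x*."""
    x = np.asarray(x, float)
    x_star = np.asarray(x_star, float)
    return np.abs(x - x_star) * np.exp(spiral_b * l) * np.cos(2 * np.pi * l) + x_star


def explore_update(x: np.ndarray, x_rand: np.ndarray,
                   A: np.ndarray | float, C: np.ndarray | float) -> np.ndarray:
    """Exploration move towards a random whale: x_rand - A * |C * x_rand - x|."""
    x = np.asarray(x, float)
    x_rand = np.asarray(x_rand, float)
    return x_rand - np.asarray(A) * np.abs(np.asarray(C) * x_rand - x)


def _a_schedule(t: int, n_iterations: int) -> float:
    """Linear decay from 2 (first iteration) to 0 (last iteration)."""
    if n_iterations == 1:
        return 0.0
    return 2.0 * (1.0 - t / (n_iterations - 1))


def optimize(fitness: FitnessSpec, cfg: WOAConfig) -> WOAResult:
    """Run WOA and return the elitist best with its fitness history.

    ``history`` has one entry per iteration after initialisation and is
    monotone non-increasing. Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_population(cfg, fitness, rng=rng)
    if not np.isfinite(state.best_fitness) and np.all(~np.isfinite(state.fitness)):
        raise ValueError("objective is non-finite on the entire initial population")
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    history = [state.best_fitness]
    for t in range(cfg.n_iterations):
        a = _a_schedule(t, cfg.n_iterations)
        new_pos = np.empty_like(state.positions)
        for i in range(cfg.n_whales):
            p = rng.random()
            q = rng.random()
            A = 2.0 * a * q - a
            C = 2.0 * rng.random()
            x = state.positions[i]
            if p < cfg.switch_prob:
                if abs(A) < 1.0:
                    cand = encircle_update(x, state.best_position, A, C)
                else:
                    j = int(rng.integers(cfg.n_whales))
                    cand = explore_update(x, state.positions[j], A, C)
                state.q = np.asarray([q])
            else:
                l = rng.uniform(-1.0, 1.0)
                cand = spiral_update(x, state.best_position, cfg.spiral_b, l)
                state.l = l
            state.p = p
            new_pos[i] = np.clip(cand, lo, hi)
            state.A = np.asarray([A])
            state.C = np.asarray([C])
        state.positions = new_pos
        state.fitness = np.array([_safe_eval(fitness, x) for x in new_pos])
        best = int(np.argmin(state.fitness))
        if state.fitness[best] < state.best_fitness:
            state.best_fitness = float(state.fitness[best])
            state.best_position = new_pos[best].copy()
        state.a = a
        state.iteration = t + 1
        history.append(state.best_fitness)
    return WOAResult(
        best_position=state.best_position.copy(),
        best_fitness=state.best_fitness,
        history=history,
        state=state,
    )
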