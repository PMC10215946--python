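"""Conventional whale optimization algorithm (WOA).

Population metaheuristic modelled on humpback bubble-net hunting.  Each
whale i holds a position X_i in a box-bounded search space and moves, per
iteration, by exactly one of three rules selected by a probability draw ρ
and the coefficient A = 2·a·rand − a with a decreasing linearly from 2 to 0:

* encircling prey   (ρ < 0.5, |A| < 1):  X′ = X_best − A·|C·X_best − X_i|
* search for prey   (ρ < 0.5, |A| ≥ 1):  X′ = X_rnd  − A·|C·X_rnd  − X_i|
* spiral bubble-net (ρ ≥ 0.5):           X′ = |X_best − X_i|·e^{c·l}·cos(2πl) + X_best

with C = 2·rand, l ~ U(−1, 1), spiral shape constant c = 1, and X_rnd a
random member of the current population.  Updates are generational; the
incumbent best (X_best) is elitist, so the best-so-far fitness trace is
non-increasing.  Out-of-bound coordinates are clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SearchSpace",
    "Population",
    "init_population",
    "decreasing_a",
    "coefficients",
    "encircling_update",
    "search_update",
    "spiral_update",
    "woa_step",
    "woa_optimize",
]

logger = logging.getLogger(__name__)

SPIRAL_SHAPE = 1.0  # logarithmic spiral constant c


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded D-dimensional continuous search space."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if lb.shape != ub.shape or lb.ndim != 1:
            raise ValueError("lb and ub must be 1-D arrays of equal length")
        if not np.all(lb < ub):
            raise ValueError("require lb < ub elementwise")
        object.__setattr__(self, "lb", lb)
        object.__setattr__(self, "ub", ub)

    @classmethod
    def unit_cube(cls, dimension: int) -> "SearchSpace":
        return cls(np.zeros(dimension), np.ones(dimension))

    @property
    def dimension(self) -> int:
        return self.lb.size

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lb, self.ub)

    def uniform(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        shape = (self.dimension,) if n is None else (n, self.dimension)
        return rng.uniform(self.lb, self.ub, size=shape)


@dataclass
class Population:
    """Whale positions with fitness and iteration state."""

    space: SearchSpace
    positions: np.ndarray  # (N, D)
    fitness: np.ndarray  # (N,)
    rng: np.random.Generator
    t: int = 0
    max_iter: int = 50
    best_position: np.ndarray = field(default=None)  # type: ignore[assignment]
    best_fitness: float = np.inf

    def __post_init__(self) -> None:
        if self.best_position is None:
            self._refresh_best()

    def _refresh_best(self) -> None:
        i = int(np.argmin(self.fitness))
        if self.fitness[i] <= self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_position = self.positions[i].copy()

    @property
    def n_whales(self) -> int:
        return self.positions.shape[0]

    @property
    def worst_position(self) -> np.ndarray:
        return self.positions[int(np.argmax(self.fitness))]


def _evaluate(cost, positions: np.ndarray) -> np.ndarray:
    fit = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        f = float(cost(x))
        if not np.isfinite(f):
            logger.warning("non-finite fitness for candidate %d; assigning +inf", i)
            f = np.inf
        fit[i] = f
    return fit


def init_population(
    space: SearchSpace,
    n_whales: int,
    seed: int | np.random.Generator,
    cost=None,
    max_iter: int = 50,
) -> Population:
    """Uniform i.i.d. initialization in [lb, ub]; deterministic under seed."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    positions = space.uniform(rng, n_whales)
    fitness = (
        _evaluate(cost, positions) if cost is not None else np.full(n_whales, np.inf)
    )
    return Population(
        space=space, positions=positions, fitness=fitness, rng=rng, max_iter=max_iter
    )


def decreasing_a(t: int, max_iter: int) -> float:
    """Linearly decreasing control parameter: a(t) = 2 − t·(2/MaxIt)."""
    return 2.0 - t * (2.0 / max_iter)


def coefficients(a: float, rng: np.random.Generator) -> tuple[float, float]:
    """A = 2·a·rand − a ∈ [−a, a];  C = 2·rand ∈ [0, 2]."""
    return 2.0 * a * rng.random() - a, 2.0 * rng.random()


def encircling_update(
    xi: np.ndarray, x_best: np.ndarray, A: float, C: float
) -> np.ndarray:
    return x_best - A * np.abs(C * x_best - xi)


def search_update(
    xi: np.ndarray, x_rnd: np.ndarray, A: float, C: float
) -> np.ndarray:
    return x_rnd - A * np.abs(C * x_rnd - xi)


def spiral_update(
    xi: np.ndarray, x_best: np.ndarray, l: float, c: float = SPIRAL_SHAPE
) -> np.ndarray:
    d = np.abs(x_best - xi)
    return d * np.exp(c * l) * np.cos(2 * np.pi * l) + x_best


def woa_step(pop: Population, cost) -> Population:
    """One generational WOA iteration (mutates and returns ``pop``)."""
    pop.t += 1
    a = decreasing_a(pop.t, pop.max_iter)
    rng = pop.rng
    new = np.empty_like(pop.positions)
    for i in range(pop.n_whales):
        rho = rng.random()
        A, C = coefficients(a, rng)
        if rho < 0.5:
            if abs(A) < 1:
                new[i] = encircling_update(pop.positions[i], pop.best_position, A, C)
            else:
                x_rnd = pop.positions[rng.integers(pop.n_whales)]
                new[i] = search_update(pop.positions[i], x_rnd, A, C)
        else:
            l = rng.uniform(-1.0, 1.0)
            new[i] = spiral_update(pop.positions[i], pop.best_position, l)
    pop.positions = pop.space.clip(new)
    pop.fitness = _evaluate(cost, pop.positions)
    pop._refresh_best()
    return pop


def woa_optimize(
    space: SearchSpace,
    cost,
    n_whales: int = 10,
    max_iter: int = 50,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run conventional WOA; returns (best position, best fitness, history).

    ``history`` is the best-so-far fitness after each of the ``max_iter``
    iterations (non-increasing).
    """
    pop = init_population(space, n_whales, seed, cost=cost, max_iter=max_iter)
    history = np.empty(max_iter)
    for t in range(max_iter):
        woa_step(pop, cost)
        history[t] = pop.best_fitness
    return pop.best_position, pop.best_fitness, history
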