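"""Enhanced whale optimization algorithm (E-WOA) and its binary variant.

E-WOA augments conventional WOA with four mechanisms:

* **Pooling** — a matrix of k stored candidates refreshed each iteration by
  a binary-mask crossover between a position sampled near the incumbent
  best (X_brnd) and the current worst whale: dimension d takes X_brnd[d]
  where the random binary vector B has a one, and X_worst[d] elsewhere.
  The new member overwrites a uniformly random existing member.
* **Migration** — a fraction of whales jumps to X_rnd − X_brnd with X_rnd
  uniform over the whole space, re-seeding exploration.
* **Preferential selection** (replaces search-for-prey) —
  X′ = X_i + A·(C·P_rnd1 − P_rnd2) with two distinct pool members.
* **Enriched encircling** (replaces encircling) —
  X′ = X_best − A·|C·X_best − P_rnd3|.

The spiral bubble-net move is unchanged.  The binary variant for feature
selection runs the same continuous dynamics in [0, 1]^D and scores each
whale through a transfer rule that thresholds coordinates into a selection
mask (empty masks are repaired to the single largest coordinate); the best
mask ever evaluated is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .woa import (
    SearchSpace,
    coefficients,
    decreasing_a,
    init_population,
    spiral_update,
    _evaluate,
)

__all__ = [
    "Pool",
    "SelectionMask",
    "update_pool",
    "sample_near_best",
    "migration_update",
    "preferential_update",
    "enriched_encircling_update",
    "binarize",
    "ewoa_minimize",
    "binary_ewoa_optimize",
    "binary_woa_optimize",
]


@dataclass
class Pool:
    """Fixed-capacity store of candidate positions (k × D)."""

    members: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.atleast_2d(np.asarray(self.members, dtype=float))

    @property
    def size(self) -> int:
        return self.members.shape[0]

    @classmethod
    def warm_up(
        cls, positions: np.ndarray, capacity: int, space: SearchSpace, rng
    ) -> "Pool":
        """Fill the pool from the initial population, topping up uniformly."""
        if capacity < 2:
            raise ValueError("pool capacity must be >= 2 (preferential selection)")
        members = positions[: min(capacity, positions.shape[0])].copy()
        if members.shape[0] < capacity:
            extra = space.uniform(rng, capacity - members.shape[0])
            members = np.vstack([members, extra])
        return cls(members)

    def sample_two(self, rng) -> tuple[np.ndarray, np.ndarray]:
        i, j = rng.choice(self.size, size=2, replace=False)
        return self.members[i], self.members[j]

    def sample_one(self, rng) -> np.ndarray:
        return self.members[rng.integers(self.size)]


@dataclass
class SelectionMask:
    """Binary feature-subset indicator."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1:
            raise ValueError("mask must be a 1-D bit vector")
        if self.selected_count < 1:
            raise ValueError("mask must select at least one feature")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def key(self) -> bytes:
        return np.packbits(self.bits).tobytes()


def sample_near_best(
    x_best: np.ndarray, space: SearchSpace, rng, radius: float = 0.1
) -> np.ndarray:
    """Uniform draw in a box of half-width radius·(ub−lb) around X_best."""
    half = radius * (space.ub - space.lb)
    return space.clip(rng.uniform(x_best - half, x_best + half))


def update_pool(
    pool: Pool, x_best: np.ndarray, x_worst: np.ndarray, space: SearchSpace, rng,
    radius: float = 0.1,
) -> Pool:
    """Crossover of a near-best sample with the worst whale; random replace.

    B is a random binary vector and B̄ its complement: the new member takes
    X_brnd where B = 1 and X_worst where B = 0, then overwrites a uniformly
    random pool member.
    """
    x_brnd = sample_near_best(x_best, space, rng, radius)
    b = rng.integers(0, 2, size=space.dimension).astype(bool)
    new_member = np.where(b, x_brnd, x_worst)
    slot = rng.integers(pool.size)
    pool.members[slot] = space.clip(new_member)
    return pool


def migration_update(space: SearchSpace, x_best: np.ndarray, rng, radius: float = 0.1) -> np.ndarray:
    """X′ = X_rnd − X_brnd, clipped; X_rnd uniform over the whole space."""
    x_rnd = space.uniform(rng)
    x_brnd = sample_near_best(x_best, space, rng, radius)
    return space.clip(x_rnd - x_brnd)


def preferential_update(
    xi: np.ndarray, A: float, C: float, pool: Pool, rng
) -> np.ndarray:
    """X′ = X_i + A·(C·P_rnd1 − P_rnd2) with distinct pool members."""
    p1, p2 = pool.sample_two(rng)
    return xi + A * (C * p1 - p2)


def enriched_encircling_update(
    xi: np.ndarray, x_best: np.ndarray, A: float, C: float, pool: Pool, rng
) -> np.ndarray:
    """X′ = X_best − A·|C·X_best − P_rnd3|."""
    p3 = pool.sample_one(rng)
    return x_best - A * np.abs(C * x_best - p3)


def binarize(
    position: np.ndarray,
    rng=None,
    transfer: str = "identity",
    threshold: float = 0.5,
) -> SelectionMask:
    """Map a continuous position in [0, 1]^D to a selection mask.

    ``identity``: bit d = 1 iff clip(position[d]) > threshold (deterministic).
    ``sigmoid``: bit d = 1 iff rand < S(position[d]) with a steep logistic
    transfer centred on the threshold (requires ``rng``).
    An all-zero mask is repaired by setting the bit of the largest coordinate.
    """
    x = np.clip(np.asarray(position, dtype=float), 0.0, 1.0)
    if transfer == "identity":
        bits = x > threshold
    elif transfer == "sigmoid":
        if rng is None:
            raise ValueError("sigmoid transfer needs an rng")
        s = 1.0 / (1.0 + np.exp(-10.0 * (x - threshold)))
        bits = rng.random(x.size) < s
    else:
        raise ValueError(f"unknown transfer {transfer!r}")
    if not bits.any():
        bits = np.zeros(x.size, dtype=bool)
        bits[int(np.argmax(x))] = True
    return SelectionMask(bits)


def ewoa_minimize(
    space: SearchSpace,
    cost,
    n_whales: int = 10,
    max_iter: int = 50,
    pool_size: int = 20,
    migration_rate: float = 0.2,
    radius: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Continuous E-WOA; returns (best position, best fitness, history).

    Per iteration: refresh the pool, pick round(migration_rate·N) whales at
    random to migrate, and move the rest by the ρ/|A| switch with
    preferential selection and enriched encircling in place of the
    conventional search/encircle rules.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    pop = init_population(space, n_whales, seed, cost=cost, max_iter=max_iter)
    rng = pop.rng
    pool = Pool.warm_up(pop.positions, pool_size, space, rng)
    n_migrate = int(round(migration_rate * n_whales))
    history = np.empty(max_iter)
    for t in range(1, max_iter + 1):
        a = decreasing_a(t, max_iter)
        update_pool(pool, pop.best_position, pop.worst_position, space, rng, radius)
        migrants = set(
            rng.choice(n_whales, size=n_migrate, replace=False).tolist()
            if n_migrate
            else []
        )
        new = np.empty_like(pop.positions)
        for i in range(n_whales):
            if i in migrants:
                new[i] = migration_update(space, pop.best_position, rng, radius)
                continue
            rho = rng.random()
            A, C = coefficients(a, rng)
            if rho < 0.5:
                if abs(A) < 1:
                    new[i] = enriched_encircling_update(
                        pop.positions[i], pop.best_position, A, C, pool, rng
                    )
                else:
                    new[i] = preferential_update(pop.positions[i], A, C, pool, rng)
            else:
                l = rng.uniform(-1.0, 1.0)
                new[i] = spiral_update(pop.positions[i], pop.best_position, l)
        pop.positions = space.clip(new)
        pop.fitness = _evaluate(cost, pop.positions)
        pop.t = t
        pop._refresh_best()
        history[t - 1] = pop.best_fitness
    return pop.best_position, pop.best_fitness, history


class _MaskedCost:
    """Binarize positions, score masks, and remember the best mask seen."""

    def __init__(self, mask_cost, rng, transfer: str, threshold: float):
        self.mask_cost = mask_cost
        self.rng = rng
        self.transfer = transfer
        self.threshold = threshold
        self.best_mask: SelectionMask | None = None
        self.best_record = None
        self.best_fitness = np.inf

    def __call__(self, position: np.ndarray) -> float:
        mask = binarize(position, self.rng, self.transfer, self.threshold)
        record = self.mask_cost(mask)
        f = float(record.fitness)
        if f < self.best_fitness:
            self.best_fitness = f
            self.best_mask = mask
            self.best_record = record
        return f


def _binary_driver(
    minimize,
    dimension: int,
    mask_cost,
    seed,
    transfer: str,
    threshold: float,
    **kwargs,
):
    space = SearchSpace.unit_cube(dimension)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    wrapped = _MaskedCost(mask_cost, rng, transfer, threshold)
    _, _, history = minimize(space, wrapped, seed=rng, **kwargs)
    return wrapped.best_mask, wrapped.best_record, history


def binary_ewoa_optimize(
    dimension: int,
    mask_cost,
    n_whales: int = 10,
    max_iter: int = 50,
    pool_size: int = 20,
    migration_rate: float = 0.2,
    radius: float = 0.1,
    transfer: str = "sigmoid",
    threshold: float = 0.5,
    seed: int | np.random.Generator = 0,
):
    """Binary E-WOA over [0,1]^D; ``mask_cost(SelectionMask) -> record``.

    The record must expose a scalar ``fitness`` (minimized).  Returns the
    best mask ever evaluated, its record, and the best-so-far history.
    """
    return _binary_driver(
        ewoa_minimize,
        dimension,
        mask_cost,
        seed,
        transfer,
        threshold,
        n_whales=n_whales,
        max_iter=max_iter,
        pool_size=pool_size,
        migration_rate=migration_rate,
        radius=radius,
    )


def binary_woa_optimize(
    dimension: int,
    mask_cost,
    n_whales: int = 10,
    max_iter: int = 50,
    transfer: str = "sigmoid",
    threshold: float = 0.5,
    seed: int | np.random.Generator = 0,
):
    """Conventional WOA driven through the same binarization (baseline)."""
    from .woa import woa_optimize

    return _binary_driver(
        woa_optimize,
        dimension,
        mask_cost,
        seed,
        transfer,
        threshold,
        n_whales=n_whales,
        max_iter=max_iter,
    )
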