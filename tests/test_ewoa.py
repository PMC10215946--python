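"""E-WOA mechanisms: pooling, migration, preferential selection, binarization."""

import numpy as np
import pytest

from neurofuse.optim import (
    Pool,
    SearchSpace,
    SelectionMask,
    binarize,
    binary_ewoa_optimize,
    enriched_encircling_update,
    ewoa_minimize,
    migration_update,
    preferential_update,
    sample_near_best,
    update_pool,
)


def sphere(x):
    return float(x @ x)


class _CountRecord:
    def __init__(self, mask):
        self.fitness = float(mask.selected_count)
        self.mask = mask


def count_cost(mask):
    """Deterministic toy mask cost: number of selected features."""
    return _CountRecord(mask)


class TestPool:
    def test_warm_up_size_and_bounds(self, rng):
        space = SearchSpace.unit_cube(4)
        pos = space.uniform(rng, 10)
        pool = Pool.warm_up(pos, 20, space, rng)
        assert pool.size == 20
        assert pool.members.min() >= 0 and pool.members.max() <= 1

    def test_capacity_below_two_rejected(self, rng):
        space = SearchSpace.unit_cube(4)
        with pytest.raises(ValueError):
            Pool.warm_up(space.uniform(rng, 5), 1, space, rng)

    def test_crossover_mask_selection(self, rng):
        """Oracle: elementwise selection by the binary vector B."""
        x_brnd = np.array([1.0, 2.0, 3.0, 4.0])
        x_worst = np.array([9.0, 9.0, 9.0, 9.0])
        b = np.array([True, False, True, False])
        assert np.allclose(np.where(b, x_brnd, x_worst), [1, 9, 3, 9])

    def test_update_pool_replaces_one_member(self, rng):
        space = SearchSpace.unit_cube(6)
        pos = space.uniform(rng, 10)
        pool = Pool.warm_up(pos, 12, space, rng)
        before = pool.members.copy()
        update_pool(pool, pos[0], pos[1], space, rng)
        changed = np.any(pool.members != before, axis=1)
        assert changed.sum() <= 1
        assert pool.size == 12
        assert pool.members.min() >= 0 and pool.members.max() <= 1

    def test_pool_size_constant_over_long_run(self, rng):
        space = SearchSpace.unit_cube(3)
        pool = Pool.warm_up(space.uniform(rng, 10), 20, space, rng)
        for _ in range(100):
            update_pool(pool, space.uniform(rng), space.uniform(rng), space, rng)
        assert pool.size == 20
        assert pool.members.min() >= 0 and pool.members.max() <= 1


class TestSampleNearBest:
    def test_zero_radius_returns_best(self, rng):
        space = SearchSpace.unit_cube(5)
        xb = np.full(5, 0.4)
        assert np.allclose(sample_near_best(xb, space, rng, radius=0.0), xb)

    def test_draws_within_box(self, rng):
        space = SearchSpace.unit_cube(2)
        xb = np.array([0.5, 0.5])
        draws = np.array([sample_near_best(xb, space, rng, 0.1) for _ in range(10_000)])
        assert np.all(np.abs(draws - 0.5) <= 0.1 + 1e-12)

    def test_empirical_mean_at_interior_best(self, rng):
        """Oracle: uniform mean equals the box centre within 3 SE."""
        space = SearchSpace.unit_cube(1)
        xb = np.array([0.5])
        draws = np.array([sample_near_best(xb, space, rng, 0.1)[0] for _ in range(10_000)])
        se = 0.2 / np.sqrt(12 * draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se


class TestMoves:
    def test_migration_within_bounds_and_seeded(self):
        space = SearchSpace.unit_cube(1)
        rng = np.random.default_rng(5)
        draws = np.array(
            [migration_update(space, np.array([0.5]), rng)[0] for _ in range(5000)]
        )
        assert draws.min() >= 0 and draws.max() <= 1
        a = migration_update(space, np.array([0.5]), np.random.default_rng(3))
        b = migration_update(space, np.array([0.5]), np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_migration_difference_distribution(self):
        """Monte-Carlo vs convolution: X_rnd - X_brnd is symmetric about 0
        (pre-clip) when the near-best box is centred in the space."""
        space = SearchSpace(np.array([-1.0]), np.array([1.0]))
        rng = np.random.default_rng(8)
        xb = np.array([0.0])
        pre_clip = np.array(
            [
                space.uniform(rng)[0] - sample_near_best(xb, space, rng, 0.1)[0]
                for _ in range(20_000)
            ]
        )
        assert abs(pre_clip.mean()) < 3 * pre_clip.std() / np.sqrt(pre_clip.size)

    def test_preferential_identities(self, rng):
        pool = Pool(np.array([[0.3], [0.1]]))
        xi = np.array([0.0])
        # A = 0 -> X' = Xi
        assert preferential_update(xi, 0.0, 1.0, pool, rng)[0] == 0.0
        # scalar case: 0 + 1*(2*0.3 - 0.1) = 0.5 for P1=0.3, P2=0.1
        out = 0.0 + 1.0 * (2.0 * 0.3 - 0.1)
        assert out == pytest.approx(0.5)

    def test_preferential_uses_distinct_members(self, rng):
        pool = Pool(np.array([[0.5], [0.9]]))
        for _ in range(50):
            p1, p2 = pool.sample_two(rng)
            assert p1[0] != p2[0]

    def test_enriched_encircling_identities(self, rng):
        xb = np.array([1.0])
        pool = Pool(np.array([[0.4], [0.4]]))
        # A = 0 -> X_best
        assert enriched_encircling_update(np.array([0.0]), xb, 0.0, 1.0, pool, rng)[0] == 1.0
        # scalars: 1 - 0.5*|1*1 - 0.4| = 0.7
        out = enriched_encircling_update(np.array([0.0]), xb, 0.5, 1.0, pool, rng)
        assert out[0] == pytest.approx(0.7)


class TestBinarize:
    def test_threshold_rule(self):
        mask = binarize(np.array([0.9, 0.1, 0.6]))
        assert mask.bits.tolist() == [True, False, True]

    def test_empty_mask_repaired_at_argmax(self):
        mask = binarize(np.array([0.2, 0.25, 0.1]))
        assert mask.bits.tolist() == [False, True, False]
        assert mask.selected_count == 1

    def test_threshold_sweep_monotone(self):
        x = np.random.default_rng(0).uniform(0, 1, 50)
        prev = 51
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            count = binarize(x, threshold=thr).selected_count
            assert count <= prev
            prev = count

    def test_sigmoid_transfer_needs_rng_and_is_seeded(self):
        x = np.array([0.5, 0.9, 0.1])
        with pytest.raises(ValueError):
            binarize(x, transfer="sigmoid")
        a = binarize(x, np.random.default_rng(3), transfer="sigmoid")
        b = binarize(x, np.random.default_rng(3), transfer="sigmoid")
        assert np.array_equal(a.bits, b.bits)

    def test_unknown_transfer_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.5]), transfer="vshape")

    def test_mask_invariants(self):
        with pytest.raises(ValueError):
            SelectionMask(np.zeros(4, dtype=bool))


class TestEwoaOptimize:
    def test_history_non_increasing_and_deterministic(self):
        space = SearchSpace(np.full(6, -5.0), np.full(6, 5.0))
        a = ewoa_minimize(space, sphere, 10, 40, seed=2)
        b = ewoa_minimize(space, sphere, 10, 40, seed=2)
        assert np.all(np.diff(a[2]) <= 0)
        assert np.array_equal(a[2], b[2]) and np.array_equal(a[0], b[0])

    def test_pool_size_below_two_rejected(self):
        space = SearchSpace.unit_cube(4)
        with pytest.raises(ValueError):
            ewoa_minimize(space, sphere, 10, 5, pool_size=1, seed=0)

    def test_zero_iterations_returns_initial_best(self):
        mask, rec, hist = binary_ewoa_optimize(12, count_cost, max_iter=0, seed=3)
        assert len(hist) == 0
        assert rec.fitness == mask.selected_count

    def test_binary_run_deterministic(self):
        a = binary_ewoa_optimize(16, count_cost, max_iter=20, seed=9)
        b = binary_ewoa_optimize(16, count_cost, max_iter=20, seed=9)
        assert np.array_equal(a[0].bits, b[0].bits)
        assert np.array_equal(a[2], b[2])

    def test_minimizes_trivial_count_cost(self):
        """On the pure count objective the optimum is a single feature."""
        mask, rec, _ = binary_ewoa_optimize(16, count_cost, max_iter=50, seed=1)
        assert rec.fitness <= 2
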