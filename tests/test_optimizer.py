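"""SSS metaheuristic: update oracles, greedy contract, convergence."""

import numpy as np
import pytest

from ecgmi.optim import (SSSConfig, fitness_mse, init_population, mean_global,
                         optimize, optimize_smo, optimize_ssd, ssd_velocity,
                         sss_update, step)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestInit:
    def test_positions_within_bounds(self):
        pop = init_population(10, 2, -3.0, 3.0, 0, sphere)
        assert np.all(pop.positions >= -3.0) and np.all(pop.positions <= 3.0)
        assert np.allclose(pop.velocities, 0.0)

    def test_same_seed_identical(self):
        a = init_population(8, 3, -1, 1, 5, sphere)
        b = init_population(8, 3, -1, 1, 5, sphere)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.fitness, b.fitness)

    def test_small_population_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            init_population(3, 2, -1, 1, 0)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="lb < ub"):
            init_population(10, 2, 1.0, 1.0, 0)


class TestFitnessMse:
    def test_equal_arrays_zero(self):
        a = np.ones((4, 2))
        assert fitness_mse(a, a) == 0.0

    def test_one_sample_two_components(self):
        assert fitness_mse(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])) == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((13, 4))
        b = rng.standard_normal((13, 4))
        total = 0.0
        for i in range(13):
            for j in range(4):
                total += (a[i, j] - b[i, j]) ** 2
        assert fitness_mse(a, b) == pytest.approx(total / (13 * 4), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            fitness_mse(np.ones(3), np.ones(4))


class TestMeanGlobal:
    def test_best_three_average(self):
        pop = init_population(4, 1, -10, 10, 0)
        pop.positions = np.array([[0.0], [3.0], [6.0], [9.0]])
        pop.fitness = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(mean_global(pop), [3.0])

    def test_identical_agents(self):
        pop = init_population(5, 2, -1, 1, 0)
        pop.positions[:] = 0.25
        pop.fitness[:] = 1.0
        assert np.allclose(mean_global(pop), 0.25)

    def test_matches_sort_then_average_oracle(self):
        rng = np.random.default_rng(4)
        pop = init_population(12, 3, -5, 5, 1)
        pop.fitness = rng.standard_normal(12)
        order = np.argsort(pop.fitness, kind="stable")[:3]
        assert np.allclose(mean_global(pop), pop.positions[order].mean(axis=0))


class TestSsdVelocity:
    def test_zero_at_consensus(self):
        p = np.array([1.0, 2.0])
        assert np.allclose(ssd_velocity(p, p, p, 1.5, 0.3, 0.2), 0.0)

    def test_zero_sine_draw(self):
        rng = np.random.default_rng(0)
        p, b, g = rng.standard_normal((3, 4))
        assert np.allclose(ssd_velocity(p, b, g, 2.0, 0.0, 0.2), 0.0)

    def test_frozen_draw_oracle_both_branches(self):
        rng = np.random.default_rng(1)
        p, b, g = rng.standard_normal((3, 5))
        l, o1 = 1.3, 0.7
        sin_v = ssd_velocity(p, b, g, l, o1, 0.4)
        assert np.allclose(sin_v, l * np.sin(o1) * (b - p) + np.sin(o1) * (g - p), atol=1e-12)
        cos_v = ssd_velocity(p, b, g, l, o1, 0.9)
        assert np.allclose(cos_v, l * np.cos(o1) * (b - p) + np.cos(o1) * (g - p), atol=1e-12)


class TestSssUpdate:
    def test_consensus_fixed_point(self):
        x_star = np.array([0.4, -1.2, 2.0])
        for o1, o01, o11 in [(0.3, 0.6, 0.2), (0.9, 0.2, -0.1), (0.0, 1.0, 0.5)]:
            cand = sss_update(x_star, x_star, x_star, x_star, x_star, 1.7, o1, o01, o11)
            assert np.allclose(cand, x_star, atol=1e-12)

    def test_frozen_scalar_example(self):
        # sine terms vanish at o1 = 0; (0.5*2 + 0.5*4)/1 = 3
        cand = sss_update(np.array([0.0]), np.array([0.0]), np.array([0.0]),
                          np.array([2.0]), np.array([4.0]), 2.0, 0.0, 0.5, 0.5)
        assert cand[0] == pytest.approx(3.0)

    def test_term_by_term_oracle_1000_frozen_draws(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            d = int(rng.integers(1, 6))
            pos, pbest, g, gl, partner = rng.standard_normal((5, d))
            l = float(rng.uniform(0, 2))
            o1 = float(rng.uniform(0, 1))
            o01 = float(rng.uniform(0, 1))
            o11 = float(rng.uniform(-1, 1))
            if abs(o01 + o11) < 1e-6:
                continue
            cand = sss_update(pos, pbest, g, gl, partner, l, o1, o01, o11)
            ssd_term = l * np.sin(o1) * (pbest - pos) + np.sin(o1) * (g - pos)
            expect = ((o01 * gl + o11 * partner) - ssd_term * (1 - o01 - o11)) / (o01 + o11)
            assert np.allclose(cand, expect, atol=1e-12)

    def test_per_dimension_draws_broadcast(self):
        rng = np.random.default_rng(5)
        pos, pbest, g, gl, partner = rng.standard_normal((5, 4))
        o1 = rng.uniform(0, 1, 4)
        o01 = rng.uniform(0, 1, 4)
        o11 = rng.uniform(-1, 1, 4)
        cand = sss_update(pos, pbest, g, gl, partner, 1.0, o1, o01, o11)
        per_dim = [sss_update(pos[d:d+1], pbest[d:d+1], g[d:d+1], gl[d:d+1],
                              partner[d:d+1], 1.0, o1[d], o01[d], o11[d])[0]
                   for d in range(4)]
        assert np.allclose(cand, per_dim, atol=1e-12)


class TestStepAndOptimize:
    def test_best_fitness_monotone_nonincreasing(self):
        pop = init_population(10, 3, -5, 5, 0, sphere)
        best = [pop.gl_fitness]
        for _ in range(30):
            step(pop, sphere, 1.0)
            best.append(pop.gl_fitness)
        assert np.all(np.diff(best) <= 0)

    def test_population_at_optimum_is_fixed_point_of_best(self):
        pop = init_population(6, 2, -5, 5, 0, sphere)
        pop.positions[:] = 0.0
        pop.fitness[:] = 0.0
        pop.pbest[:] = 0.0
        pop.pbest_fitness[:] = 0.0
        pop.gl[:] = 0.0
        pop.gl_fitness = 0.0
        step(pop, sphere, 1.0)
        assert pop.gl_fitness == 0.0

    def test_sphere_convergence_over_20_seeds(self):
        finals = [optimize(sphere, 2, SSSConfig(y=30, K=100, lb=-5, ub=5, seed=s)).fitness
                  for s in range(20)]
        assert np.median(finals) < 1e-2

    def test_trace_length_and_monotonicity(self):
        res = optimize(sphere, 3, SSSConfig(y=10, K=40, lb=-2, ub=2, seed=1))
        assert len(res.trace) <= 40
        assert np.all(np.diff(res.trace) <= 0)

    def test_deterministic_under_seed(self):
        a = optimize(sphere, 2, SSSConfig(y=8, K=25, lb=-1, ub=1, seed=3))
        b = optimize(sphere, 2, SSSConfig(y=8, K=25, lb=-1, ub=1, seed=3))
        assert np.array_equal(a.position, b.position)
        assert a.trace == b.trace

    def test_positions_remain_within_bounds(self):
        pop = init_population(8, 4, -0.5, 0.5, 2, sphere)
        for _ in range(20):
            step(pop, sphere, 2.0)
        assert np.all(pop.positions >= -0.5) and np.all(pop.positions <= 0.5)

    def test_nonfinite_objective_candidates_rejected(self):
        def holey(x):
            v = sphere(x)
            return np.nan if v < 0.5 else v
        res = optimize(holey, 2, SSSConfig(y=8, K=30, lb=-3, ub=3, seed=0))
        assert np.isfinite(res.fitness)

    def test_hybrid_within_10x_of_best_baseline(self):
        cfg = lambda s: SSSConfig(y=30, K=100, lb=-5, ub=5, seed=s)
        sss = np.median([optimize(sphere, 2, cfg(s)).fitness for s in range(10)])
        ssd = np.median([optimize_ssd(sphere, 2, cfg(s)).fitness for s in range(10)])
        smo = np.median([optimize_smo(sphere, 2, cfg(s)).fitness for s in range(10)])
        # below 1e-12 the sphere is numerically converged for all methods
        assert sss <= 10 * max(min(ssd, smo), 1e-12)

    def test_early_stop_on_stalled_improvement(self):
        res = optimize(sphere, 2, SSSConfig(y=10, K=500, lb=-1, ub=1, seed=0,
                                            tol=1e-14, patience=5))
        assert res.n_iterations < 500
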