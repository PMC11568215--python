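"""Optimizer coefficient schedules, single moves, and loop invariants."""

import math

import numpy as np
import pytest

from mwoa import optimizers
from mwoa.optimizers import (
    OptimizerConfig,
    SearchSpace,
    compute_coefficients_mwoa1,
    compute_coefficients_standard,
    diffusion_walk,
    encircle_update,
    explore_update,
    optimize,
    optimize_benchmark,
    spiral_update,
)


def sphere(pop):
    return np.sum(np.asarray(pop) ** 2, axis=1)


class TestCoefficients:
    def test_standard_schedule_endpoints(self, rng):
        assert compute_coefficients_standard(1, 100, rng).a == 2.0
        assert compute_coefficients_standard(100, 100, rng).a == 0.0

    def test_standard_A_bounded_by_a(self, rng):
        for it in (1, 7, 50, 100):
            c = compute_coefficients_standard(it, 100, rng, dimension=5)
            assert np.all(np.abs(c.A) <= c.a + 1e-12)

    def test_modified_schedule_start(self, rng):
        c = compute_coefficients_mwoa1(1, 100, rng)
        assert c.a == 2.0
        assert c.a2 == -1.0

    def test_modified_final_a_in_cos_image(self, rng):
        # at the last iteration a = 2 - cos(r), r in [0, 1]
        for _ in range(50):
            c = compute_coefficients_mwoa1(100, 100, rng)
            assert 2.0 - math.cos(0.0) - 1e-12 <= c.a <= 2.0 - math.cos(1.0) + 1e-12

    def test_modified_A_within_sine_envelope(self, rng):
        for _ in range(50):
            c = compute_coefficients_mwoa1(40, 100, rng, dimension=3)
            assert np.all(c.A >= -c.a - 1e-12)
            assert np.all(c.A <= c.a * math.sin(1.0) + 1e-12)

    def test_iteration_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_coefficients_standard(0, 10, rng)
        with pytest.raises(ValueError):
            compute_coefficients_mwoa1(11, 10, rng)


class TestSingleMoves:
    def test_encircle_with_zero_A_returns_best(self):
        best = np.array([1.0, -2.0])
        out = encircle_update(np.array([5.0, 5.0]), best, np.zeros(2), np.ones(2))
        np.testing.assert_array_equal(out, best)

    def test_encircle_hand_example(self):
        out = encircle_update(
            np.array([1.0, 1.0]), np.array([0.0, 0.0]), np.array([1.0, 1.0]), np.array([2.0, 2.0])
        )
        np.testing.assert_allclose(out, [-1.0, -1.0])

    def test_encircle_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            encircle_update(np.zeros(2), np.zeros(3), 1.0, 1.0)

    def test_spiral_fixed_point_at_best(self):
        best = np.array([2.0, 3.0])
        np.testing.assert_array_equal(spiral_update(best, best, l=0.3), best)

    def test_spiral_hand_example(self):
        out = spiral_update(np.array([0.0]), np.array([1.0]), l=0.0, spiral_constant=1.0)
        assert out[0] == pytest.approx(2.0)

    def test_spiral_sign_flips_with_cosine(self):
        x, best = np.array([0.0]), np.array([1.0])
        inner = spiral_update(x, best, l=0.2)[0] - 1.0
        outer = spiral_update(x, best, l=0.3)[0] - 1.0
        assert inner > 0 > outer  # cos(2*pi*l) changes sign at l = 0.25

    def test_spiral_printed_distance_needs_C(self):
        with pytest.raises(ValueError, match="printed"):
            spiral_update(np.zeros(2), np.ones(2), l=0.1, distance="printed")

    def test_explore_fixed_points(self):
        x_rand = np.array([4.0, -1.0])
        np.testing.assert_array_equal(
            explore_update(x_rand, x_rand, np.array([2.0]), np.ones(2)), x_rand
        )
        np.testing.assert_array_equal(
            explore_update(np.array([9.0, 9.0]), x_rand, np.zeros(1), np.ones(2)), x_rand
        )

    def test_explore_hand_example(self):
        out = explore_update(np.array([0.0]), np.array([4.0]), np.array([2.0]), np.array([0.5]))
        assert out[0] == pytest.approx(0.0)

    def test_diffusion_degenerate_inputs(self):
        rng = np.random.default_rng(0)
        zero = np.zeros(3)
        np.testing.assert_array_equal(diffusion_walk(zero, zero, rng), zero)

    def test_diffusion_reproducible(self):
        a = diffusion_walk(np.array([1.0]), np.array([0.0]), np.random.default_rng(7))
        b = diffusion_walk(np.array([1.0]), np.array([0.0]), np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestOptimizeLoop:
    @pytest.mark.parametrize("variant", optimizers.VARIANTS)
    def test_seeded_determinism(self, variant):
        cfg = OptimizerConfig(variant=variant, n_agents=8, max_iter=40, seed=5)
        r1 = optimize_benchmark("F16", cfg)
        r2 = optimize_benchmark("F16", cfg)
        assert r1.best_value == r2.best_value
        np.testing.assert_array_equal(r1.history, r2.history)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    @pytest.mark.parametrize("variant", optimizers.VARIANTS)
    def test_history_non_increasing_and_final(self, variant):
        res = optimize_benchmark(
            "F9", OptimizerConfig(variant=variant, n_agents=6, max_iter=50, seed=3)
        )
        assert np.all(np.diff(res.history) <= 0)
        assert res.history[-1] == res.best_value

    def test_best_position_within_bounds(self):
        from mwoa.benchmarks import get_spec

        for fid in ("F8", "F17"):
            spec = get_spec(fid)
            res = optimize_benchmark(
                fid, OptimizerConfig(variant="mwoa2", n_agents=6, max_iter=30, seed=1)
            )
            assert np.all(res.best_position >= spec.lower_bound)
            assert np.all(res.best_position <= spec.upper_bound)

    def test_evaluation_accounting_single_iteration(self):
        k = 9
        cfg = OptimizerConfig(variant="woa", n_agents=k, max_iter=1, seed=0)
        space = SearchSpace(np.full(3, -1.0), np.full(3, 1.0))
        res = optimize(sphere, space, cfg)
        assert res.n_evaluations == 2 * k

    def test_non_finite_objective_resamples(self):
        calls = {"n": 0}

        def nasty(pop):
            calls["n"] += 1
            vals = sphere(pop)
            if calls["n"] == 1:
                vals = vals.copy()
                vals[0] = np.nan
            return vals

        cfg = OptimizerConfig(variant="woa", n_agents=5, max_iter=3, seed=2)
        res = optimize(nasty, SearchSpace(np.full(2, -1.0), np.full(2, 1.0)), cfg)
        assert np.isfinite(res.best_value)

    def test_sphere_parameter_recovery(self):
        # deep convergence on the 2-D sphere in at least 29 of 30 runs
        space = SearchSpace(np.full(2, -100.0), np.full(2, 100.0))
        wins = sum(
            optimize(sphere, space, OptimizerConfig(variant="mwoa2", seed=50 + r)).best_value
            < 1e-10
            for r in range(30)
        )
        assert wins >= 29

    def test_mwoa2_sphere_30d(self):
        res = optimize_benchmark("F1", OptimizerConfig(variant="mwoa2", seed=0))
        assert res.best_value <= 1e-8

    def test_variant_equivalence_without_exploration(self, monkeypatch):
        # with exploration forced off and pure spiral moves, woa and
        # mwoa2 share identical trajectories under the same seed
        monkeypatch.setattr(
            optimizers, "_exploration_mask", lambda A: np.zeros(A.shape[0], dtype=bool)
        )
        space = SearchSpace(np.full(2, -5.0), np.full(2, 5.0))
        kwargs = dict(
            n_agents=6, max_iter=25, seed=9, switch_probability=1.0, diffusion_walks=0
        )
        r_woa = optimize(sphere, space, OptimizerConfig(variant="woa", **kwargs))
        r_mwoa2 = optimize(sphere, space, OptimizerConfig(variant="mwoa2", **kwargs))
        np.testing.assert_array_equal(r_woa.history, r_mwoa2.history)
        np.testing.assert_array_equal(r_woa.best_position, r_mwoa2.best_position)

    def test_multi_walk_diffusion_counts_extra_evaluations(self):
        cfg1 = OptimizerConfig(variant="mwoa2", n_agents=6, max_iter=20, seed=4)
        cfg3 = OptimizerConfig(
            variant="mwoa2", n_agents=6, max_iter=20, seed=4, diffusion_walks=3
        )
        space = SearchSpace(np.full(2, -5.0), np.full(2, 5.0))
        assert (
            optimize(sphere, space, cfg3).n_evaluations
            >= optimize(sphere, space, cfg1).n_evaluations
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OptimizerConfig(variant="nope")
        with pytest.raises(ValueError):
            OptimizerConfig(n_agents=1)
        with pytest.raises(ValueError):
            OptimizerConfig(switch_probability=1.5)

    def test_result_serialisation_round_trips(self):
        import json

        res = optimize_benchmark(
            "F16", OptimizerConfig(variant="woa", n_agents=5, max_iter=10, seed=1)
        )
        payload = json.loads(res.to_json())
        assert payload["best_value"] == res.best_value
        assert payload["n_evaluations"] == res.n_evaluations
        assert res.history_csv().splitlines()[0] == "iteration,best_so_far"
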