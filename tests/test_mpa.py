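"""Unit and property tests for the Marine Predators Algorithm optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpapnn.mpa import (
    ConvergenceTrace,
    EliteState,
    MPAConfig,
    Population,
    SearchSpace,
    compute_cf,
    fads_perturbation,
    initialize_population,
    mantegna_sigma_u,
    optimize,
    phase_for_iteration,
    phase_update,
    sample_brownian,
    sample_levy,
)


def sphere(x):
    return float((x**2).sum())


class TestSearchSpace:
    def test_equal_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace([2.0], [2.0])

    def test_crossed_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace([0.0, 1.0], [1.0, 0.5])

    def test_clamp_projects_to_box(self):
        space = SearchSpace([0.0, -1.0], [1.0, 1.0])
        clamped = space.clamp(np.array([[2.0, -3.0], [0.5, 0.0]]))
        assert clamped.tolist() == [[1.0, -1.0], [0.5, 0.0]]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 0},
            {"max_iterations": 0},
            {"fads_probability": 1.5},
            {"levy_exponent": 0.0},
            {"levy_exponent": 2.5},
            {"patience": 0},
            {"fads_w_convention": "bogus"},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            MPAConfig(**kwargs)

    def test_defaults_match_benchmark_settings(self):
        cfg = MPAConfig()
        assert (cfg.population_size, cfg.max_iterations) == (10, 100)
        assert cfg.fads_probability == 0.2
        assert cfg.levy_exponent == 1.5
        assert cfg.step_constant == 0.5
        assert cfg.patience is None


class TestInitialization:
    def test_positions_within_bounds(self):
        space = SearchSpace.unit(5)
        pop, elite, _ = initialize_population(space, MPAConfig(seed=3), sphere)
        assert pop.positions.shape == (10, 5)
        assert (pop.positions >= 0).all() and (pop.positions <= 1).all()

    def test_seeded_determinism(self):
        space = SearchSpace.unit(4)
        a, _, _ = initialize_population(space, MPAConfig(seed=9), sphere)
        b, _, _ = initialize_population(space, MPAConfig(seed=9), sphere)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_elite_is_population_best(self):
        space = SearchSpace([-5.0] * 3, [5.0] * 3)
        pop, elite, _ = initialize_population(space, MPAConfig(seed=1), sphere)
        assert elite.memory_fitness.shape == (10,)
        np.testing.assert_array_equal(elite.memory_positions, pop.positions)

    def test_non_finite_objective_rejected(self):
        space = SearchSpace.unit(2)
        with pytest.raises(ValueError, match="non-finite"):
            initialize_population(space, MPAConfig(seed=1), lambda x: float("inf"))


class TestSamplers:
    def test_brownian_moments(self, rng):
        draws = sample_brownian(100_000, 1, rng).ravel()
        assert abs(draws.mean()) < 0.02
        assert abs(draws.var() - 1.0) < 0.03

    def test_brownian_density_peak(self, rng):
        # histogram density near 0 matches the standard-normal peak 1/sqrt(2*pi)
        draws = sample_brownian(100_000, 1, rng).ravel()
        in_bin = np.mean(np.abs(draws) < 0.05)
        assert abs(in_bin / 0.1 - 1.0 / np.sqrt(2 * np.pi)) < 0.02

    def test_brownian_columns_independent(self, rng):
        draws = sample_brownian(100_000, 2, rng)
        corr = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(corr) < 0.02

    def test_mantegna_sigma_value(self):
        assert mantegna_sigma_u(1.5) == pytest.approx(0.6966, abs=1e-4)

    def test_levy_beta_validation(self, rng):
        with pytest.raises(ValueError):
            sample_levy(10, 1, 2.5, rng)
        with pytest.raises(ValueError):
            sample_levy(10, 1, 0.0, rng)

    def test_levy_beta2_tail_is_gaussian(self, rng):
        draws = sample_levy(1_000_000, 1, 2.0, rng).ravel()
        # at beta=2 the construction is a normal ratio-free draw scaled by
        # sigma_u; |x|>6 should be essentially absent
        assert np.mean(np.abs(draws) > 6.0) < 1e-4

    def test_levy_heavier_tail_than_gaussian(self, rng):
        levy = sample_levy(1_000_000, 1, 1.5, rng).ravel()
        gauss = sample_brownian(1_000_000, 1, rng).ravel()
        assert np.mean(np.abs(levy) > 10.0) > np.mean(np.abs(gauss) > 10.0)


class TestCF:
    @pytest.mark.parametrize(
        "t,t_max,expected",
        [(0, 100, 1.0), (100, 100, 0.0), (50, 100, 0.5 ** np.sqrt(2))],
    )
    def test_closed_form_values(self, t, t_max, expected):
        assert compute_cf(t, t_max) == pytest.approx(expected, abs=1e-5)

    def test_midpoint_value(self):
        assert compute_cf(50, 100) == pytest.approx(0.37521, abs=1e-5)

    def test_strictly_decreasing(self):
        values = [compute_cf(t, 200) for t in range(201)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compute_cf(101, 100)
        with pytest.raises(ValueError):
            compute_cf(-1, 100)


class TestPhaseSchedule:
    @pytest.mark.parametrize("t,phase", [(10, 1), (50, 2), (90, 3), (0, 1), (33, 1), (34, 2), (66, 2), (67, 3)])
    def test_schedule_thirds(self, t, phase):
        assert phase_for_iteration(t, 100) == phase

    @given(st.integers(min_value=1, max_value=500))
    @settings(max_examples=50, deadline=None)
    def test_every_iteration_has_exactly_one_phase(self, t_max):
        for t in range(t_max):
            assert phase_for_iteration(t, t_max) in (1, 2, 3)


class _FakeRng:
    """Deterministic generator stub: fixed normal and uniform values."""

    def __init__(self, normal=0.5, uniform=1.0):
        self._normal = normal
        self._uniform = uniform

    def standard_normal(self, shape):
        return np.full(shape, self._normal)

    def uniform(self, size=None, **kw):
        return np.full(size, self._uniform)

    def integers(self, low, high, size=None):
        return np.zeros(size, dtype=int)


def _tiny_state(u_value, elite_value, t_max=100):
    space = SearchSpace.unit(1)
    pop = Population(positions=np.array([[u_value]]), fitness=np.array([0.0]))
    elite = EliteState(
        elite_position=np.array([elite_value]),
        elite_fitness=0.0,
        memory_positions=np.array([[u_value]]),
        memory_fitness=np.array([0.0]),
    )
    return space, pop, elite


class TestPhaseUpdate:
    def test_phase1_hand_computation(self):
        # S = R_B*(Elite - R_B*U) = 0.5*(0.8 - 0.5*0.2) = 0.35
        # U' = U + P*R*S = 0.2 + 0.5*1*0.35 = 0.375
        space, pop, elite = _tiny_state(0.2, 0.8)
        cfg = MPAConfig(max_iterations=100, population_size=1, seed=0)
        out = phase_update(pop, elite, t=10, config=cfg, space=space, rng=_FakeRng())
        assert out.positions[0, 0] == pytest.approx(0.375)

    def test_phase1_zero_noise_leaves_positions(self):
        space, pop, elite = _tiny_state(0.3, 0.9)
        cfg = MPAConfig(max_iterations=100, population_size=1, seed=0)
        out = phase_update(
            pop, elite, t=5, config=cfg, space=space, rng=_FakeRng(normal=0.0)
        )
        assert out.positions[0, 0] == pytest.approx(0.3)

    def test_dimension_mismatch_raises(self):
        space = SearchSpace.unit(2)
        pop = Population(positions=np.zeros((3, 1)), fitness=np.zeros(3))
        elite = EliteState(np.zeros(1), 0.0, np.zeros((3, 1)), np.zeros(3))
        with pytest.raises(ValueError):
            phase_update(pop, elite, 0, MPAConfig(), space, np.random.default_rng(0))

    @pytest.mark.parametrize("t", [5, 50, 90])
    def test_positions_stay_bounded(self, t, rng):
        space = SearchSpace.unit(4)
        cfg = MPAConfig(population_size=8, max_iterations=100, seed=0)
        pop, elite, gen = initialize_population(space, cfg, sphere)
        out = phase_update(pop, elite, t, cfg, space, gen)
        assert (out.positions >= 0).all() and (out.positions <= 1).all()


class TestFadsPerturbation:
    def test_zero_fads_probability_uses_drift_branch(self, rng):
        space = SearchSpace.unit(3)
        cfg = MPAConfig(population_size=6, fads_probability=0.0, seed=0)
        pop, elite, gen = initialize_population(space, cfg, sphere)
        before = pop.positions.copy()
        out = fads_perturbation(pop, elite, 10, cfg, space, gen)
        # drift branch: moves along differences of other prey, never the
        # masked box jump; positions remain in bounds
        assert (out.positions >= 0).all() and (out.positions <= 1).all()
        assert not np.array_equal(out.positions, before)  # overwhelmingly likely

    def test_cf_zero_jump_branch_is_identity(self):
        space = SearchSpace.unit(2)
        cfg = MPAConfig(population_size=4, fads_probability=1.0, max_iterations=50, seed=0)
        pop, elite, gen = initialize_population(space, cfg, sphere)
        before = pop.positions.copy()
        out = fads_perturbation(pop, elite, 50, cfg, space, gen)  # CF(t_max)=0
        np.testing.assert_allclose(out.positions, before)

    def test_single_individual_falls_back_to_jump_branch(self):
        space = SearchSpace.unit(2)
        cfg = MPAConfig(population_size=1, fads_probability=0.0, seed=0)
        pop, elite, gen = initialize_population(space, cfg, sphere)
        out = fads_perturbation(pop, elite, 1, cfg, space, gen)
        assert (out.positions >= 0).all() and (out.positions <= 1).all()

    @pytest.mark.parametrize("convention", ["sparse", "paper_literal"])
    def test_output_bounded_under_both_mask_conventions(self, convention):
        space = SearchSpace([-2.0] * 3, [2.0] * 3)
        cfg = MPAConfig(population_size=10, fads_w_convention=convention, seed=4)
        pop, elite, gen = initialize_population(space, cfg, sphere)
        out = fads_perturbation(pop, elite, 3, cfg, space, gen)
        assert (out.positions >= -2).all() and (out.positions <= 2).all()


class TestOptimize:
    def test_constant_objective_flat_trace(self):
        space = SearchSpace.unit(3)
        cfg = MPAConfig(population_size=5, max_iterations=20, seed=2)
        _, best, trace = optimize(lambda x: 3.0, space, cfg)
        assert best == 3.0
        assert trace.best_fitness_per_iteration == [3.0] * 20

    def test_trace_monotone_and_bounded_random_objective(self):
        rng = np.random.default_rng(0)
        coeffs = rng.uniform(0.5, 2.0, size=6)

        def objective(x):
            return float((coeffs * np.abs(x - 0.3)).sum())

        space = SearchSpace.unit(6)
        cfg = MPAConfig(population_size=8, max_iterations=60, seed=5)
        pos, best, trace = optimize(objective, space, cfg)
        values = trace.best_fitness_per_iteration
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert (pos >= 0).all() and (pos <= 1).all()
        assert best == values[-1]

    def test_maximization_trace_non_decreasing(self):
        space = SearchSpace.unit(4)
        cfg = MPAConfig(population_size=6, max_iterations=40, seed=3)
        _, best, trace = optimize(lambda x: float(x.sum()), space, cfg, "maximize")
        values = trace.best_fitness_per_iteration
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert best <= 4.0

    def test_seeded_determinism_full_trace(self):
        space = SearchSpace([-1.0] * 3, [1.0] * 3)
        cfg = MPAConfig(population_size=6, max_iterations=30, seed=11)
        r1 = optimize(sphere, space, cfg)
        r2 = optimize(sphere, space, cfg)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[2].best_fitness_per_iteration == r2[2].best_fitness_per_iteration

    def test_patience_stops_early_on_constant(self):
        space = SearchSpace.unit(2)
        cfg = MPAConfig(population_size=4, max_iterations=100, patience=5, seed=1)
        _, _, trace = optimize(lambda x: 1.0, space, cfg)
        assert trace.iterations_executed == 5

    def test_objective_error_carries_iteration_context(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] > 12:
                return float("nan")
            return sphere(x)

        space = SearchSpace.unit(2)
        cfg = MPAConfig(population_size=4, max_iterations=10, seed=1)
        with pytest.raises(ValueError, match="iteration"):
            optimize(flaky, space, cfg)

    def test_trace_csv_export(self, tmp_path):
        space = SearchSpace.unit(2)
        cfg = MPAConfig(population_size=4, max_iterations=5, seed=1)
        _, _, trace = optimize(sphere, space, cfg)
        out = tmp_path / "trace.csv"
        trace.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "iteration,best_fitness"
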