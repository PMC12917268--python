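"""Sparrow-cougar optimizer: forced-draw update algebra and run contracts."""

import numpy as np
import pytest

from seizeeg.optim import (
    OptimizerConfig,
    SparrowCougarOptimizer,
    danger_position,
    producer_position,
    random_search,
    rosenbrock,
    scrounger_position,
    sphere,
)


def _config(**kwargs):
    defaults = dict(dimension=3, population_size=10, max_iterations=100, seed=0)
    return OptimizerConfig(**{**defaults, **kwargs})


class TestProducerUpdate:
    def test_calm_branch_matches_direct_formula(self):
        """rank 2, gamma 0.5, i_max 100: M * exp(-2 / 50) ~ 0.9608 M."""
        cfg = _config(max_iterations=100, safety_threshold=0.8)
        pos = np.ones(3)
        new, vel = producer_position(
            pos, rank=2, config=cfg, alarm=0.3, gamma=0.5, normal_draw=0.0,
            velocity=np.zeros(3), q1=0.7, best_position=np.zeros(3),
        )
        np.testing.assert_allclose(new, np.exp(-2 / 50.0) * pos, atol=1e-12)
        np.testing.assert_array_equal(vel, np.zeros(3))  # velocity untouched when calm

    def test_alarmed_branch_fixed_point(self):
        """With zero velocity, q1 = 0 and N = 0 the alarmed move is
        0.5 M + 0.5 M = M."""
        cfg = _config()
        pos = np.array([1.0, -2.0, 0.5])
        new, vel = producer_position(
            pos, rank=1, config=cfg, alarm=0.95, gamma=0.5, normal_draw=0.0,
            velocity=np.zeros(3), q1=0.0, best_position=np.array([5.0, 5.0, 5.0]),
        )
        np.testing.assert_allclose(new, pos, atol=1e-12)
        np.testing.assert_array_equal(vel, np.zeros(3))

    def test_alarmed_at_best_moves_only_by_noise(self):
        """At M = M_best the velocity increment vanishes; motion is the
        N * ones sparrow term halved."""
        cfg = _config()
        pos = np.array([1.0, 2.0, 3.0])
        new, vel = producer_position(
            pos, rank=1, config=cfg, alarm=0.9, gamma=0.5, normal_draw=0.4,
            velocity=np.zeros(3), q1=0.8, best_position=pos.copy(),
        )
        np.testing.assert_array_equal(vel, np.zeros(3))
        np.testing.assert_allclose(new, pos + 0.2, atol=1e-12)  # 0.5 * N

    def test_alarmed_velocity_accumulates_toward_best(self):
        cfg = _config(cougar_constant=2.0)
        pos = np.zeros(3)
        best = np.ones(3)
        _, vel = producer_position(
            pos, rank=1, config=cfg, alarm=0.9, gamma=0.5, normal_draw=0.0,
            velocity=np.full(3, 0.1), q1=0.5, best_position=best,
        )
        np.testing.assert_allclose(vel, 0.1 + 0.5 * 2.0 * 1.0)


class TestScroungerUpdate:
    def test_follower_at_producer_stays_there(self):
        cfg = _config(population_size=10)
        producer = np.array([1.0, 2.0, 3.0])
        new = scrounger_position(
            producer.copy(), rank=4, config=cfg, gamma=0.5,
            normal_draws=np.zeros(3), signs=np.array([1.0, -1.0, 1.0]),
            worst_position=np.zeros(3), producer_pos=producer,
        )
        np.testing.assert_allclose(new, producer, atol=1e-12)

    def test_one_dimensional_pseudoinverse_closed_form(self):
        """k = 1, Q = [1]: Q+ . S = 1, so the move is M_P + |M_u - M_P|."""
        cfg = _config(dimension=1, population_size=10)
        new = scrounger_position(
            np.array([2.0]), rank=3, config=cfg, gamma=0.5,
            normal_draws=np.zeros(1), signs=np.array([1.0]),
            worst_position=np.zeros(1), producer_pos=np.array([5.0]),
        )
        np.testing.assert_allclose(new, np.array([5.0 + 3.0]), atol=1e-12)

    def test_starving_branch_at_worst_returns_the_draw(self):
        """M_u = M_bad makes the exponent vanish: new position = N per
        coordinate."""
        cfg = _config(population_size=10)
        draws = np.array([0.3, -1.1, 0.7])
        worst = np.array([1.0, 1.0, 1.0])
        new = scrounger_position(
            worst.copy(), rank=8, config=cfg, gamma=0.5,
            normal_draws=draws, signs=np.ones(3),
            worst_position=worst, producer_pos=np.zeros(3),
        )
        np.testing.assert_allclose(new, draws, atol=1e-12)


class TestDangerUpdate:
    def test_row_at_best_position_with_best_displacement_zero(self):
        """First branch at M_u = M_good: the |difference| term vanishes."""
        cfg = _config()
        best = np.array([1.0, 2.0, 3.0])
        new = danger_position(
            best.copy(), score=0.5, config=cfg, gamma=0.7, x_draw=0.3,
            best_position=best, best_score=1.0,
            worst_position=np.zeros(3), worst_score=0.0,
        )
        np.testing.assert_allclose(new, best, atol=1e-12)

    def test_flat_fitness_escape_step_scaled_by_alpha(self):
        """At m_u = m_n = m_w the step is X * |M_u - M_bad| / alpha: large
        but finite because alpha > 0."""
        cfg = _config(alpha=1e-8)
        pos = np.array([1.0, 1.0, 1.0])
        worst = np.array([0.0, 0.0, 0.0])
        new = danger_position(
            pos, score=0.5, config=cfg, gamma=0.7, x_draw=0.25,
            best_position=pos, best_score=0.5,
            worst_position=worst, worst_score=0.5,
        )
        np.testing.assert_allclose(new - pos, 0.25 * np.abs(pos - worst) / 1e-8)

    def test_x_zero_leaves_best_row_unchanged(self):
        cfg = _config()
        pos = np.array([2.0, -1.0, 0.0])
        new = danger_position(
            pos, score=0.9, config=cfg, gamma=0.3, x_draw=0.0,
            best_position=pos, best_score=0.9,
            worst_position=np.ones(3), worst_score=0.1,
        )
        np.testing.assert_allclose(new, pos, atol=1e-12)


class TestInitialize:
    def test_seeded_initialization_is_identical(self):
        cfg = _config(seed=5)
        opt = SparrowCougarOptimizer(cfg)
        a = opt.initialize(sphere, np.random.default_rng(cfg.seed))
        b = opt.initialize(sphere, np.random.default_rng(cfg.seed))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_degenerate_bounds_collapse_positions(self):
        cfg = _config(bounds=(0.0, 0.0))
        pop = SparrowCougarOptimizer(cfg).initialize(sphere, np.random.default_rng(0))
        np.testing.assert_array_equal(pop.positions, np.zeros_like(pop.positions))

    def test_uniform_sampling_is_centred(self):
        cfg = _config(dimension=5, population_size=100, bounds=(-5.0, 5.0))
        pop = SparrowCougarOptimizer(cfg).initialize(sphere, np.random.default_rng(1))
        assert np.all(np.abs(pop.positions.mean(axis=0)) < 0.5)

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            _config(population_size=1)


class TestRun:
    def test_trace_is_deterministic_under_seed(self):
        cfg = _config(dimension=4, max_iterations=30, orientation="minimize", seed=9)
        a = SparrowCougarOptimizer(cfg).run(sphere)
        b = SparrowCougarOptimizer(cfg).run(sphere)
        assert a.trace == b.trace
        np.testing.assert_array_equal(a.x, b.x)

    def test_elitist_best_is_monotone(self):
        cfg = _config(dimension=5, max_iterations=50, orientation="minimize")
        res = SparrowCougarOptimizer(cfg).run(sphere)
        best = res.best_trace
        assert np.all(np.diff(best) <= 0)  # minimization: non-increasing

    def test_positions_stay_in_bounds_every_iteration(self):
        seen = []
        cfg = _config(dimension=3, max_iterations=25, bounds=(-1.5, 1.5), orientation="minimize")

        def recording(x):
            seen.append(x.copy())
            return sphere(x)

        SparrowCougarOptimizer(cfg).run(recording)
        seen = np.array(seen)
        assert np.all(seen >= -1.5) and np.all(seen <= 1.5)

    def test_zero_iterations_returns_best_initial(self):
        cfg = _config(dimension=3, max_iterations=0, orientation="minimize", seed=2)
        res = SparrowCougarOptimizer(cfg).run(sphere)
        pop = SparrowCougarOptimizer(cfg).initialize(sphere, np.random.default_rng(2))
        assert res.fun == pop.scores.min()
        assert res.n_iterations == 0

    def test_objective_errors_carry_iteration_context(self):
        cfg = _config(max_iterations=3)

        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] > cfg.population_size:
                raise RuntimeError("boom")
            return sphere(x)

        with pytest.raises(RuntimeError):
            SparrowCougarOptimizer(cfg).run(flaky)

    def test_improves_sphere_substantially(self):
        cfg = _config(
            dimension=5, population_size=30, max_iterations=100,
            bounds=(-5.0, 5.0), orientation="minimize", seed=3,
        )
        res = SparrowCougarOptimizer(cfg).run(sphere)
        assert res.fun < 1e-3 * res.trace[0]["best"]

    def test_beats_random_search_on_rosenbrock(self):
        cfg = _config(
            dimension=5, population_size=30, max_iterations=100,
            bounds=(-5.0, 5.0), orientation="minimize", seed=4,
        )
        assert SparrowCougarOptimizer(cfg).run(rosenbrock).fun <= random_search(rosenbrock, cfg).fun


@pytest.mark.parametrize(
    "kwargs",
    [
        {"safety_threshold": 0.3},
        {"danger_fraction": 0.0},
        {"producer_fraction": 1.0},
        {"bounds": (2.0, -2.0)},
        {"orientation": "sideways"},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        _config(**kwargs)
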