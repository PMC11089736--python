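"""Morris screening: trajectory geometry, elementary-effect oracles,
importance classification and iterated removal."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cardiotwin import morris


def exhaustive_mu_star(func, n_dim, z=4):
    """Brute-force mu*: every grid start point x every change order.

    With step Delta = z/(2(z-1)) > 1/2 each coordinate has exactly one
    feasible direction, so start x order enumerates all trajectories.
    """
    levels = np.arange(z) / (z - 1)
    delta = 0.5 * z / (z - 1)
    abs_effects = []
    for start in itertools.product(levels, repeat=n_dim):
        for order in itertools.permutations(range(n_dim)):
            x = np.array(start)
            ee = np.empty(n_dim)
            for i in order:
                step = delta if x[i] + delta <= 1.0 + 1e-12 else -delta
                x_new = x.copy()
                x_new[i] += step
                ee[i] = (func(x_new) - func(x)) / step
                x = x_new
            abs_effects.append(np.abs(ee))
    return np.mean(abs_effects, axis=0)


class TestTrajectory:
    def test_structure(self, rng):
        cfg = morris.MorrisConfig(z=8)
        traj = morris.build_trajectory(3, cfg, rng)
        assert traj.points.shape == (4, 3)
        for k in range(3):
            diff = traj.points[k + 1] - traj.points[k]
            changed = np.flatnonzero(diff != 0)
            assert changed.size == 1
            assert abs(diff[changed[0]]) == pytest.approx(cfg.delta)
        assert np.all(traj.points >= 0) and np.all(traj.points <= 1)

    def test_step_size_for_eight_levels(self):
        assert morris.MorrisConfig(z=8).delta == pytest.approx(4.0 / 7.0)

    def test_odd_levels_rejected(self):
        with pytest.raises(ValueError):
            morris.MorrisConfig(z=7)

    def test_start_points_uniform_on_grid(self, rng):
        """Chi-square goodness of fit of start levels vs uniform."""
        cfg = morris.MorrisConfig(z=8)
        starts = np.array([morris.build_trajectory(1, cfg, rng).points[0, 0]
                           for _ in range(20000)])
        counts = np.array([(np.abs(starts - lv / 7.0) < 1e-12).sum()
                           for lv in range(8)])
        assert counts.sum() == 20000
        p = stats.chisquare(counts).pvalue
        assert p > 1e-4


class TestElementaryEffects:
    def test_linear_function_exact(self, rng):
        a = np.array([3.0, -2.0, 0.5])
        cfg = morris.MorrisConfig(z=8)
        for _ in range(10):
            traj = morris.build_trajectory(3, cfg, rng)
            y = traj.points @ a
            ee = morris.elementary_effects(traj, y)
            np.testing.assert_allclose(ee[:, 0], a, atol=1e-12)

    def test_inert_parameter_zero_effect(self, rng):
        cfg = morris.MorrisConfig(z=8)
        traj = morris.build_trajectory(3, cfg, rng)
        y = traj.points[:, 0] * 2.0  # independent of x2, x3
        ee = morris.elementary_effects(traj, y)
        assert ee[1, 0] == 0.0 and ee[2, 0] == 0.0

    def test_failed_evaluation_voids_trajectory(self, rng):
        cfg = morris.MorrisConfig(z=8)
        traj = morris.build_trajectory(2, cfg, rng)
        y = np.array([1.0, np.nan, 2.0])
        with pytest.raises(ValueError):
            morris.elementary_effects(traj, y)

    def test_mu_star_matches_exhaustive_oracle(self):
        """Sampled mu* for Y = x1*x2 agrees with full enumeration at
        z = 4 within Monte-Carlo error."""
        func = lambda x: x[0] * x[1]
        oracle = exhaustive_mu_star(func, 2, z=4)
        cfg = morris.MorrisConfig(z=4, min_traj=2000, max_traj=2000,
                                  batch=100)
        rng = np.random.default_rng(7)
        effects = []
        for _ in range(2000):
            traj = morris.build_trajectory(2, cfg, rng)
            y = np.array([func(p) for p in traj.points])
            effects.append(morris.elementary_effects(traj, y))
        sampled = morris.mu_star(np.stack(effects))[:, 0]
        np.testing.assert_allclose(sampled, oracle, rtol=0.05)

    def test_additive_three_dim_exact(self):
        a = np.array([1.0, -4.0, 2.5])
        func = lambda x: float(x @ a)
        oracle = exhaustive_mu_star(func, 3, z=4)
        np.testing.assert_allclose(oracle, np.abs(a), atol=1e-12)


class TestClassification:
    def test_single_parameter_always_kept(self):
        assert morris.classify_importance(np.array([[0.3]]))[0]

    def test_dominant_vs_negligible(self):
        mu = np.array([[10.0, 10.0], [0.01, 0.01]])
        keep = morris.classify_importance(mu)
        assert keep[0] and not keep[1]

    def test_equal_coefficients_all_kept(self):
        mu = np.full((5, 2), 3.3)
        assert morris.classify_importance(mu).all()

    def test_ci_overrides_point_estimate(self):
        mu = np.array([[10.0], [1.0]])
        ci_up = np.array([[12.0], [7.0]])  # CI of the small one spans the mean
        keep = morris.classify_importance(mu, ci_up)
        assert keep[0] and keep[1]


class TestConvergence:
    def test_identical_trajectories_converged(self):
        ee = np.tile(np.array([[3.0], [0.1]]), (10, 1, 1))
        assert morris.converged(ee)

    def test_borderline_flip_not_converged(self):
        # one outlier trajectory decides parameter 2's importance
        base = np.tile(np.array([[1.0], [0.9]]), (10, 1, 1))
        outlier = np.array([[[1.0], [50.0]]])
        stack = np.concatenate([base, outlier])
        assert not morris.converged(stack)


class TestScreening:
    def test_all_important_single_iteration(self, rng):
        cfg = morris.MorrisConfig(z=8, min_traj=50, batch=10, max_traj=200)
        evaluate = lambda x: np.array([x @ np.array([1.0, 1.0])])
        keep, log = morris.msm_iterate(evaluate, 2, cfg, rng)
        assert keep.all()
        assert len(log.iterations) == 1

    def test_dummy_parameter_removed(self, rng):
        cfg = morris.MorrisConfig(z=8, min_traj=50, batch=10, max_traj=200)
        evaluate = lambda x: np.array([10.0 * x[0] + 10.0 * x[1] + 1e-4 * x[2]])
        keep, log = morris.msm_iterate(evaluate, 3, cfg, rng)
        assert keep[0] and keep[1] and not keep[2]
        assert len(log.iterations) >= 2  # removal then fixed point

    def test_success_rate_logged_with_failures(self, rng):
        cfg = morris.MorrisConfig(z=8, min_traj=30, batch=10, max_traj=100)

        def evaluate(x):
            if x[0] > 0.9:  # a slice of the space fails
                return None
            return np.array([x[0] + x[1]])

        entry = {}
        morris.screen(evaluate, 2, cfg, rng, log=entry)
        assert 0.0 < entry["success_rate"] < 1.0
        assert entry["n_traj"] >= 30

    def test_budget_exhaustion_uses_bootstrap(self, rng):
        cfg = morris.MorrisConfig(z=8, min_traj=20, batch=5, max_traj=30,
                                  n_boot=200)
        # two near-identical parameters with heavy output noise: the
        # keep/remove split sits on the mean, so leave-one-out keeps
        # flipping and the budget runs out
        evaluate = lambda x: np.array([x[0] + x[1]
                                       + 2.0 * float(rng.standard_normal())])
        result = morris.screen(evaluate, 2, cfg, rng)
        assert result.ci_upper is not None
        assert result.n_traj == 30
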