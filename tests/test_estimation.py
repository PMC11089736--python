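"""DMS-PSO: known-optimum recovery, contracts, determinism."""

import numpy as np
import pytest

from cardiotwin import estimation as est
from cardiotwin import forward_model as fm
from cardiotwin import registry as reg


@pytest.fixture(scope="module")
def sphere_space(registry6_module):
    """A 3-D subset whose specs provide bounds for a synthetic objective."""
    subset = registry6_module.select(["q0", "p0", "ADO_LV"])
    base = fm.reference_parameters(registry6_module)
    return est.ParameterSpace(subset, base)


@pytest.fixture(scope="module")
def registry6_module():
    return reg.apply_segmentation(reg.build_homogeneous_registry(), 6)


def normalized_sphere(space, center_unit=0.6):
    lo, hi = space.mc_lo, space.mc_hi
    center = lo + center_unit * (hi - lo)

    def objective(x):
        if np.any(x < space.pso_lo) or np.any(x > space.pso_hi):
            return np.inf
        u = (np.asarray(x) - center) / (hi - lo)
        return float((u ** 2).sum())

    return objective, center


class TestDmsPso:
    def test_sphere_optimum_recovered(self, sphere_space):
        """Median over 5 seeds: optimum found within 1e-3 of the range."""
        objective, center = normalized_sphere(sphere_space)
        errs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            cfg = est.SwarmConfig(particles=24, n_swarms=8, mc_pool=100,
                                  max_iter=2000)
            x0, f0 = est.mc_initialize(sphere_space, objective, cfg, rng)
            res = est.dms_pso(x0, objective, sphere_space, cfg, rng,
                              initial_costs=f0)
            err = np.abs(res.best_x - center) / sphere_space.mc_width
            errs.append(err.max())
        assert np.median(errs) < 1e-3

    def test_velocity_clamp_respected(self, sphere_space):
        """Per-iteration particle displacement never exceeds 25% of the
        extended input-space width (positions spied via the objective)."""
        objective, _ = normalized_sphere(sphere_space)
        rng = np.random.default_rng(0)
        cfg = est.SwarmConfig(particles=6, n_swarms=2, mc_pool=30,
                              max_iter=25)
        x0, f0 = est.mc_initialize(sphere_space, objective, cfg, rng)
        probes = []

        def spying_objective(x):
            probes.append(np.array(x))
            return objective(x)

        res = est.dms_pso(x0, spying_objective, sphere_space, cfg, rng,
                          initial_costs=f0)
        assert res.best_chi2 <= f0.min()
        pos = np.array(probes).reshape(-1, cfg.particles, sphere_space.n_dim)
        steps = np.abs(np.diff(np.concatenate([x0[None], pos]), axis=0))
        vmax = cfg.velocity_frac * sphere_space.pso_width
        assert np.all(steps <= vmax[None, None, :] + 1e-12)

    def test_out_of_bounds_infinite(self, sphere_space):
        objective, _ = normalized_sphere(sphere_space)
        assert objective(sphere_space.pso_hi + 1.0) == np.inf

    def test_gbest_monotone_nonincreasing(self, sphere_space):
        objective, _ = normalized_sphere(sphere_space)
        rng = np.random.default_rng(1)
        cfg = est.SwarmConfig(particles=12, n_swarms=4, mc_pool=50,
                              max_iter=100)
        x0, f0 = est.mc_initialize(sphere_space, objective, cfg, rng)
        res = est.dms_pso(x0, objective, sphere_space, cfg, rng,
                          initial_costs=f0)
        assert np.all(np.diff(res.history) <= 0)

    def test_always_infinite_objective_fails(self, sphere_space):
        rng = np.random.default_rng(0)
        cfg = est.SwarmConfig(particles=6, n_swarms=2, mc_pool=20,
                              max_iter=10)
        x0 = np.tile(sphere_space.mc_lo, (6, 1))
        with pytest.raises(RuntimeError):
            est.dms_pso(x0, lambda x: np.inf, sphere_space, cfg, rng)


class TestMcInitialize:
    def test_within_screening_ranges(self, sphere_space):
        objective, _ = normalized_sphere(sphere_space)
        rng = np.random.default_rng(2)
        cfg = est.SwarmConfig(particles=12, n_swarms=4, mc_pool=60)
        x0, f0 = est.mc_initialize(sphere_space, objective, cfg, rng,
                                   constraints=[])
        assert np.all(x0 >= sphere_space.mc_lo)
        assert np.all(x0 <= sphere_space.mc_hi)
        assert np.all(np.diff(np.sort(f0)) >= 0)

    def test_seeded_determinism(self, sphere_space):
        objective, _ = normalized_sphere(sphere_space)
        cfg = est.SwarmConfig(particles=12, n_swarms=4, mc_pool=60)
        a, _ = est.mc_initialize(sphere_space, objective, cfg,
                                 np.random.default_rng(5))
        b, _ = est.mc_initialize(sphere_space, objective, cfg,
                                 np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_dyssynchrony_constraint_applied(self, registry6_module):
        subset = reg.build_estimation_subset(registry6_module, ["dT"])
        base = fm.reference_parameters(registry6_module)
        space = est.ParameterSpace(subset, base)
        rng = np.random.default_rng(0)
        cfg = est.SwarmConfig(particles=12, n_swarms=4, mc_pool=50)
        x0, _ = est.mc_initialize(space, lambda x: float((x ** 2).sum()),
                                  cfg, rng)
        assert np.all(x0.max(axis=1) - x0.min(axis=1) <= 130.0)


class TestRepeatedEstimation:
    def test_identical_seeds_identical_repeats(self, lbbb_patient6,
                                               registry6_module):
        subset = registry6_module.select(["q0"])
        base = fm.reference_parameters(registry6_module)
        cfg = est.SwarmConfig(particles=6, n_swarms=2, mc_pool=30,
                              max_iter=30, repeats=2)
        r1 = est.repeated_estimation(lbbb_patient6.measurement, subset,
                                     base, cfg, seed=9)
        r2 = est.repeated_estimation(lbbb_patient6.measurement, subset,
                                     base, cfg, seed=9)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.best_x, b.best_x)
            assert a.best_chi2 == b.best_chi2

    def test_chi2_never_above_mc_best(self, lbbb_patient6, registry6_module):
        subset = registry6_module.select(["q0"])
        base = fm.reference_parameters(registry6_module)
        cfg = est.SwarmConfig(particles=6, n_swarms=2, mc_pool=30,
                              max_iter=30, repeats=3)
        results = est.repeated_estimation(lbbb_patient6.measurement, subset,
                                          base, cfg, seed=1)
        assert len(results) == 3
        for r in results:
            assert r.best_chi2 <= r.mc_best_chi2


def test_particles_divisible_by_swarms():
    with pytest.raises(ValueError):
        est.SwarmConfig(particles=10, n_swarms=3)
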