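"""Bundled LV model: symmetry, equilibrium, determinism, strain post-processing."""

import numpy as np
import pytest

from cardiotwin import features
from cardiotwin import forward_model as fm
from cardiotwin.forward_model import (
    ED_STRETCH, L_GEO, ModelParameterError, end_diastolic_volume,
    fiber_strain, scale_strain_to_measurement, simulate,
    solve_wall_equilibrium, _solve_equilibrium_numpy,
)


class TestSimulate:
    def test_homogeneous_segments_identical(self, reference_sim6):
        for i in range(1, 6):
            np.testing.assert_allclose(reference_sim6.strain[i],
                                       reference_sim6.strain[0])

    def test_stroke_volume_matches_cardiac_output(self, reference_params6,
                                                  reference_sim6):
        q0 = reference_params6.scalars["q0"]
        tc = reference_params6.scalars["tCycle"]
        sv = reference_sim6.volume.max() - reference_sim6.volume.min()
        assert sv == pytest.approx(q0 * tc / 1000.0, rel=0.01)

    def test_strain_zero_at_mitral_closure(self, heterogeneous_sim6):
        np.testing.assert_allclose(heterogeneous_sim6.strain[:, 0], 0.0,
                                   atol=1e-12)

    def test_events_ordered(self, reference_sim6):
        ev = reference_sim6.events
        assert ev["t0"] <= ev["AVO"] < ev["AVC"] <= reference_sim6.time[-1]

    def test_volume_positive(self, heterogeneous_sim6):
        assert np.all(heterogeneous_sim6.volume > 0)

    def test_deterministic_bitwise(self, reference_params6):
        a = simulate(reference_params6)
        b = simulate(reference_params6)
        assert np.array_equal(a.strain, b.strain)
        assert np.array_equal(a.volume, b.volume)

    def test_later_delay_shifts_shortening_onset(self, reference_params6):
        base = reference_params6.copy()
        base.segmental["dT"][:] = [0, 20, 40, 60, 80, 100]
        later = base.copy()
        later.segmental["dT"][3] = 90.0
        f0 = features.strain_indices(*_seg(simulate(base), 3))
        f1 = features.strain_indices(*_seg(simulate(later), 3))
        assert f1["t_sh50"] > f0["t_sh50"]

    def test_missing_parameter_raises(self, reference_params6):
        broken = reference_params6.copy()
        del broken.scalars["q0"]
        with pytest.raises(ModelParameterError):
            simulate(broken)

    def test_nonphysiological_flagged_not_raised(self, reference_params6):
        bad = reference_params6.copy()
        bad.scalars["q0"] = 1000.0  # SV far above EDV
        result = simulate(bad)
        assert result.success is False

    def test_stiffer_segment_stretches_less_late_diastole(self,
                                                          reference_params6):
        p = reference_params6.copy()
        p.segmental["dT"][:] = [0, 20, 40, 60, 80, 100]
        stiff = p.copy()
        stiff.segmental["k1"][2] *= 3.0
        soft_sim, stiff_sim = simulate(p), simulate(stiff)
        late = soft_sim.time > 0.8 * p.scalars["tCycle"]
        soft_amp = np.ptp(soft_sim.strain[2][late])
        stiff_amp = np.ptp(stiff_sim.strain[2][late])
        assert stiff_amp < soft_amp


def _seg(sim, i):
    return sim.time, sim.strain[i], sim.events


class TestWallEquilibrium:
    def _inputs(self, params, n_seg=6, het=True):
        tc = params.scalars["tCycle"]
        nt = int(np.ceil(tc / 2.0)) + 1
        t = np.linspace(0, tc, nt)
        edv = end_diastolic_volume(params.effective("AmRef").sum())
        vol, _, _ = fm._volume_template(t, tc, params.scalars["q0"] * tc / 1000,
                                        edv, 0.0)
        area = ED_STRETCH * ((vol + edv) / (2 * edv)) ** (2 / 3)
        dT = np.array([0, 20, 40, 60, 80, 100.0]) if het else np.zeros(6)
        act = fm._activation(t, tc, dT, params.scalars["ADO_LV"],
                             params.effective("vMax"), params.effective("TR"),
                             params.effective("TD"), params.effective("LDAD"),
                             params.effective("LDCI"))
        return area, params.effective("AmRef"), \
            params.effective("SfAct")[:, None] * act, \
            params.effective("SfPas"), params.effective("k1"), \
            params.effective("Ls0Pas")

    def test_residual_below_threshold(self, reference_params6):
        area, am, A, P, K, L0 = self._inputs(reference_params6)
        L, T, ok = solve_wall_equilibrium(area, am, A, P, K, L0)
        assert ok
        w = am / am.sum()
        resid = np.abs((w[:, None] * L).sum(0) / L_GEO - area) / area
        assert resid.max() < 1e-8

    def test_identical_segments_equal_strain(self, reference_params6):
        area, am, A, P, K, L0 = self._inputs(reference_params6, het=False)
        L, _, ok = solve_wall_equilibrium(area, am, A, P, K, L0)
        assert ok
        np.testing.assert_allclose(L, np.broadcast_to(L[:1], L.shape),
                                   atol=1e-7)

    def test_amref_scale_invariance(self, reference_params6):
        """Doubling every AmRef with a fixed area template leaves the
        per-segment lengths unchanged."""
        area, am, A, P, K, L0 = self._inputs(reference_params6)
        L1, _, _ = solve_wall_equilibrium(area, am, A, P, K, L0)
        L2, _, _ = solve_wall_equilibrium(area, 2.0 * am, A, P, K, L0)
        np.testing.assert_allclose(L1, L2, rtol=1e-9)

    def test_noncontractile_segment_stretches(self, reference_params6):
        p = reference_params6.copy()
        p.segmental["SfAct"][2] = 1e-9
        sim = simulate(p)
        assert sim.success
        systole = (sim.time > sim.events["AVO"]) & (sim.time < sim.events["AVC"])
        assert sim.strain[2][systole].max() > 5.0     # stretches
        assert sim.strain[0][systole].min() < -5.0    # others shorten

    def test_compiled_and_vectorized_paths_agree(self, reference_params6, rng):
        """The per-column kernel and the vectorized solver are two
        independent implementations of the same equilibrium."""
        for _ in range(5):
            p = reference_params6.copy()
            p.segmental["SfAct"] = rng.uniform(20, 160, 6)
            p.segmental["k1"] = rng.uniform(5, 40, 6)
            p.segmental["SfPas"] = rng.uniform(0.1, 6, 6)
            p.segmental["dT"] = rng.uniform(0, 120, 6)
            args = self._inputs(p)
            L1, T1, ok1 = solve_wall_equilibrium(*args)
            L2, T2, ok2 = _solve_equilibrium_numpy(*args)
            assert ok1 and ok2
            np.testing.assert_allclose(L1, L2, atol=1e-9)


class TestStrainPostprocessing:
    def test_constant_length_zero_strain(self):
        t = np.arange(0, 100.0, 2.0)
        eps = fiber_strain(t, np.full(t.size, 2.0), t0=0.0)
        np.testing.assert_array_equal(eps, 0.0)

    def test_ten_percent_shortening(self):
        t = np.array([0.0, 1.0])
        eps = fiber_strain(t, np.array([2.0, 1.8]), t0=0.0)
        assert eps[1] == pytest.approx(-10.0)

    def test_zero_at_reference_any_trace(self, rng):
        t = np.linspace(0, 100, 51)
        ls = 2.0 + 0.2 * rng.standard_normal(51) ** 2 + 0.1
        eps = fiber_strain(t, ls, t0=t[10])
        assert eps[10] == pytest.approx(0.0, abs=1e-12)

    def test_t0_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            fiber_strain(np.array([0.0, 1.0]), np.array([2.0, 2.0]), t0=5.0)

    def test_scaling_identity_and_ratio(self):
        strain = np.array([[0, -5, -10, -5.0], [0, -3, -6, -3.0]])
        glob_peak = strain.mean(axis=0).min()
        np.testing.assert_allclose(
            scale_strain_to_measurement(strain, glob_peak), strain)
        doubled = scale_strain_to_measurement(strain, 2 * glob_peak)
        np.testing.assert_allclose(doubled, 2 * strain)

    def test_scaled_global_peak_matches_measurement(self, heterogeneous_sim6):
        scaled = scale_strain_to_measurement(heterogeneous_sim6.strain, -20.0)
        glob = scaled.mean(axis=0)
        assert glob[np.argmin(glob)] == pytest.approx(-20.0)

    def test_zero_simulated_peak_rejected(self):
        with pytest.raises(ValueError):
            scale_strain_to_measurement(np.zeros((3, 10)), -20.0)
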