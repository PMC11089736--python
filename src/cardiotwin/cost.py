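"""Goodness-of-fit between simulated and measured LV mechanics.

The total cost is a mean squared error over dimensionless contributors:

    chi2 = (chi2_VED + chi2_EF + chi2_eps + chi2_epsdot) / (2 + 2*n_seg)

with volume terms normalized by measurement uncertainties proportional
to the measured values (0.13 * V_ED and 0.14 * EF), and strain /
strain-rate terms averaged over the comparison-window samples per
segment and normalized by sigma_eps = 2 % and sigma_epsdot = 20 %/s.

For identifiability analysis the cost gains a cycle-time deviation term
with doubled weight:

    chi2_IA = (chi2_VED + chi2_EF + chi2_eps + chi2_epsdot
               + 2*chi2_tcycle) / (4 + 2*n_seg),
    chi2_tcycle = ((tCycle - t_cycle_mea) / 50 ms)^2.

Only strain from mitral valve closure until 10% global re-lengthening
plus 50 ms enters the cost, excluding late-diastolic strain.  Simulated
fiber strain is first scaled to the measured global strain amplitude and
resampled (linear interpolation) to the measurement time base; strain
rate is computed after resampling, on the measurement grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from . import features
from .forward_model import SimulationResult, scale_strain_to_measurement


@dataclass
class MeasurementSet:
    """A (real or virtual) patient's strain and volume measurements."""

    time: np.ndarray       # ms, device sampling grid
    strain: np.ndarray     # (n_seg, nt), longitudinal strain in %
    v_ed: float            # measured end-diastolic volume, mL
    ef: float              # measured ejection fraction, %
    t_cycle: float         # measured cycle time, ms
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.atleast_2d(np.asarray(self.strain, dtype=float))
        if self.strain.shape[1] != self.time.size:
            raise ValueError("strain traces and time base disagree")
        if self.v_ed <= 0:
            raise ValueError("V_ED must be positive")
        if not (0.0 < self.ef < 100.0):
            raise ValueError("EF must be in (0, 100) %")

    @property
    def n_seg(self) -> int:
        return self.strain.shape[0]

    @property
    def global_strain(self) -> np.ndarray:
        return self.strain.mean(axis=0)

    @property
    def global_peak(self) -> float:
        g = self.global_strain
        return float(g[np.argmin(g)])


@dataclass
class CostConfig:
    sigma_ved_factor: float = 0.13   # of measured V_ED
    sigma_ef_factor: float = 0.14    # of measured EF
    sigma_eps: float = 2.0           # %
    sigma_epsdot: float = 20.0       # %/s
    sigma_tcycle: float = 50.0       # ms
    window_extra_ms: float = 50.0

    def __post_init__(self) -> None:
        for name in ("sigma_ved_factor", "sigma_ef_factor", "sigma_eps",
                     "sigma_epsdot", "sigma_tcycle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def comparison_window(time: np.ndarray, global_strain: np.ndarray,
                      extra_ms: float = 50.0) -> tuple:
    """Window [t0, t_end] for strain comparison.

    ``t_end`` is the first time the global signal recovers 10% of its
    peak-to-final re-lengthening span, plus ``extra_ms``; the window
    start is mitral valve closure (the start of the trace).
    """
    time = np.asarray(time, dtype=float)
    g = np.asarray(global_strain, dtype=float)
    i_min = int(np.argmin(g))
    peak = g[i_min]
    span = g[-1] - peak
    if span <= 1e-12:
        raise ValueError("no global re-lengthening detected")
    level = peak + 0.10 * span
    t10 = features._first_crossing(time[i_min:], g[i_min:], level,
                                   downward=False)
    if not np.isfinite(t10):
        raise ValueError("no global re-lengthening detected")
    return float(time[0]), min(float(t10 + extra_ms), float(time[-1]))


def resample_to_measurement(sim: SimulationResult,
                            meas: MeasurementSet) -> np.ndarray:
    """Scaled simulated strain on the measurement time base.

    Applies the global-amplitude scaling, then linear interpolation of
    every segmental trace onto the measurement sampling grid.
    """
    scaled = scale_strain_to_measurement(sim.strain, meas.global_peak)
    out = np.empty((scaled.shape[0], meas.time.size))
    for i in range(scaled.shape[0]):
        out[i] = np.interp(meas.time, sim.time, scaled[i])
    return out


class CostContext:
    """Precomputed measurement-side quantities for repeated scoring.

    Building the comparison window, the measured strain rate and the
    normalization factors once makes the per-simulation cost evaluation
    cheap inside optimization and sampling loops.
    """

    def __init__(self, meas: MeasurementSet,
                 cfg: Optional[CostConfig] = None,
                 scale_to_measurement: bool = True) -> None:
        self.meas = meas
        self.cfg = cfg = cfg or CostConfig()
        self.scale_to_measurement = scale_to_measurement
        t0, t_end = comparison_window(meas.time, meas.global_strain,
                                      cfg.window_extra_ms)
        self.window = (meas.time >= t0) & (meas.time <= t_end)
        self.n_dp = int(self.window.sum())
        if self.n_dp < 3:
            raise ValueError("comparison window too short")
        self.time_s = meas.time / 1000.0
        self.sr_mea = np.gradient(meas.strain, self.time_s, axis=1)
        self.global_peak = meas.global_peak

    def components(self, sim: SimulationResult) -> Dict[str, float]:
        meas, cfg, win = self.meas, self.cfg, self.window
        if sim.n_seg != meas.n_seg:
            raise ValueError(f"segment schemes differ: sim {sim.n_seg}, "
                             f"measurement {meas.n_seg}")
        edv_mod, sv_mod = features.volume_outputs(sim.volume)
        ef_mod = 100.0 * sv_mod / edv_mod
        chi2_ved = ((edv_mod - meas.v_ed)
                    / (cfg.sigma_ved_factor * meas.v_ed)) ** 2
        chi2_ef = ((ef_mod - meas.ef) / (cfg.sigma_ef_factor * meas.ef)) ** 2

        if self.scale_to_measurement:
            glob = sim.strain.mean(axis=0)
            peak = glob[np.argmin(glob)]
            if peak == 0.0:
                raise ValueError("simulated global strain peak is zero")
            scale = self.global_peak / peak
        else:
            scale = 1.0
        sim_eps = np.empty((sim.n_seg, meas.time.size))
        for i in range(sim.n_seg):
            sim_eps[i] = np.interp(meas.time, sim.time, sim.strain[i])
        sim_eps *= scale

        d_eps = (sim_eps[:, win] - meas.strain[:, win]) / cfg.sigma_eps
        eps_seg = (d_eps ** 2).sum(axis=1) / self.n_dp

        sr_sim = np.gradient(sim_eps, self.time_s, axis=1)
        d_sr = (sr_sim[:, win] - self.sr_mea[:, win]) / cfg.sigma_epsdot
        sr_seg = (d_sr ** 2).sum(axis=1) / self.n_dp

        return {
            "chi2_VED": float(chi2_ved),
            "chi2_EF": float(chi2_ef),
            "chi2_eps": float(eps_seg.sum()),
            "chi2_epsdot": float(sr_seg.sum()),
            "chi2_eps_seg": eps_seg,
            "chi2_epsdot_seg": sr_seg,
            "n_dp": self.n_dp,
        }

    def chi2(self, sim: SimulationResult) -> float:
        if not sim.success:
            return np.inf
        return chi2_total(self.components(sim), self.meas.n_seg)


def chi2_components(sim: SimulationResult, meas: MeasurementSet,
                    cfg: Optional[CostConfig] = None,
                    scale_to_measurement: bool = True) -> Dict[str, float]:
    """The four dimensionless cost contributors, plus per-segment terms.

    Returns a dict with ``chi2_VED``, ``chi2_EF``, ``chi2_eps``,
    ``chi2_epsdot`` and arrays ``chi2_eps_seg`` / ``chi2_epsdot_seg``
    holding each segment's contribution (used for component-wise
    identifiability scoring).  By default simulated strain is first
    scaled to the measured global amplitude; pass
    ``scale_to_measurement=False`` to compare pre-scaled traces.
    """
    return CostContext(meas, cfg, scale_to_measurement).components(sim)


def chi2_total(components: Dict[str, float], n_seg: int) -> float:
    """Mean-squared-error cost: summed contributors over 2 + 2*n_seg."""
    s = (components["chi2_VED"] + components["chi2_EF"]
         + components["chi2_eps"] + components["chi2_epsdot"])
    return s / (2.0 + 2.0 * n_seg)


def chi2_tcycle_term(t_cycle_mod: float, t_cycle_mea: float,
                     cfg: Optional[CostConfig] = None) -> float:
    cfg = cfg or CostConfig()
    return float(((t_cycle_mod - t_cycle_mea) / cfg.sigma_tcycle) ** 2)


def chi2_ia(components: Dict[str, float], chi2_tcycle: float,
            n_seg: int) -> float:
    """Identifiability-analysis cost with doubled cycle-time weight."""
    s = (components["chi2_VED"] + components["chi2_EF"]
         + components["chi2_eps"] + components["chi2_epsdot"]
         + 2.0 * chi2_tcycle)
    return s / (4.0 + 2.0 * n_seg)


def evaluate(sim: SimulationResult, meas: MeasurementSet,
             cfg: Optional[CostConfig] = None) -> Dict[str, float]:
    """Total cost and contributors for one simulation, or infinity if
    the simulation failed."""
    if not sim.success:
        return {"chi2": np.inf, "chi2_VED": np.inf, "chi2_EF": np.inf,
                "chi2_eps": np.inf, "chi2_epsdot": np.inf}
    comps = chi2_components(sim, meas, cfg)
    return {
        "chi2": chi2_total(comps, meas.n_seg),
        "chi2_VED": comps["chi2_VED"], "chi2_EF": comps["chi2_EF"],
        "chi2_eps": comps["chi2_eps"], "chi2_epsdot": comps["chi2_epsdot"],
    }
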