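"""Strain, strain-rate and volume outputs of interest.

Per myocardial segment, 12 strain indices and 4 strain-rate indices
summarize the morphology and amplitude of the strain signal over one
cycle; the two volume outputs are end-diastolic volume (EDV) and stroke
volume (SV).  These scalars are the sensitivity-screening outputs and
the feature vocabulary used throughout the pipeline.

Window conventions (the zero-strain reference is mitral valve closure,
``t0``): systole is ``[t0, AVC]`` and ejection ``[AVO, AVC]``, with AVO
and AVC the aortic valve opening/closure events.  Timing indices that
are undefined on a trace (no shortening, or no re-lengthening) are
reported as NaN sentinels so that downstream screening can treat them as
model failure rather than silent zeros.
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

import numpy as np

STRAIN_INDEX_NAMES = (
    "eps_min", "eps_min_sys", "d_eps_post", "d_eps_pre", "d_eps_ej",
    "mean_eps_sys", "mean_eps_ej",
    "t_sh10", "t_sh50", "t_sh90", "t_rel10", "t_rel50",
)
STRAIN_RATE_INDEX_NAMES = (
    "sr_min_sys", "sr_min_ej", "mean_sr_sys", "mean_sr_ej",
)


def _first_crossing(time: np.ndarray, trace: np.ndarray, level: float,
                    downward: bool) -> float:
    """First time the trace crosses ``level`` (linear interpolation)."""
    y = trace - level
    if downward:
        y = -y
    above = y >= 0.0
    if above[0]:
        return float(time[0])
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return np.nan
    j = idx[0]
    y0, y1 = y[j - 1], y[j]
    frac = -y0 / (y1 - y0)
    return float(time[j - 1] + frac * (time[j] - time[j - 1]))


def strain_indices(time: np.ndarray, trace: np.ndarray,
                   events: Mapping[str, float]) -> Dict[str, float]:
    """The 12 strain indices of one segmental trace (strain in %).

    * ``eps_min``: peak (most negative) strain over the cycle.
    * ``eps_min_sys``: peak systolic strain, the minimum on [t0, AVC].
    * ``d_eps_post``: post-systolic shortening, |eps_min - eps_min_sys|.
    * ``d_eps_pre``: pre-ejection stretch, the positive excursion on
      [t0, AVO].
    * ``d_eps_ej``: ejection stretch, the summed positive (stretching)
      increments on [AVO, AVC].
    * ``mean_eps_sys`` / ``mean_eps_ej``: time averages over systole and
      ejection.
    * ``t_sh,x``: first time strain reaches x% of peak shortening.
    * ``t_rel,x``: first post-peak time strain recovers x% of the
      peak-to-end re-lengthening span.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    t0, avo, avc = events["t0"], events["AVO"], events["AVC"]
    if not (time[0] <= t0 <= avo < avc <= time[-1]):
        raise ValueError("valve events outside the trace")
    sys_mask = (time >= t0) & (time <= avc)
    ej_mask = (time >= avo) & (time <= avc)
    pre_mask = (time >= t0) & (time <= avo)

    eps_min = float(trace.min())
    eps_min_sys = float(trace[sys_mask].min())
    d_eps_post = abs(eps_min - eps_min_sys)
    d_eps_pre = max(float(trace[pre_mask].max()), 0.0)
    dej = np.diff(trace[ej_mask])
    d_eps_ej = float(dej[dej > 0].sum())
    mean_eps_sys = float(np.trapezoid(trace[sys_mask], time[sys_mask])
                         / (time[sys_mask][-1] - time[sys_mask][0])) \
        if sys_mask.sum() > 1 else float(trace[sys_mask][0])
    mean_eps_ej = float(np.trapezoid(trace[ej_mask], time[ej_mask])
                        / (time[ej_mask][-1] - time[ej_mask][0])) \
        if ej_mask.sum() > 1 else float(trace[ej_mask][0])

    out = {
        "eps_min": eps_min, "eps_min_sys": eps_min_sys,
        "d_eps_post": d_eps_post, "d_eps_pre": d_eps_pre,
        "d_eps_ej": d_eps_ej, "mean_eps_sys": mean_eps_sys,
        "mean_eps_ej": mean_eps_ej,
    }
    if eps_min >= 0.0:  # no shortening: timing undefined
        for name in ("t_sh10", "t_sh50", "t_sh90", "t_rel10", "t_rel50"):
            out[name] = np.nan
        return out
    for x in (10, 50, 90):
        out[f"t_sh{x}"] = _first_crossing(time, trace, 0.01 * x * eps_min,
                                          downward=True)
    i_min = int(np.argmin(trace))
    span = trace[-1] - eps_min
    if span <= 0.0:
        out["t_rel10"] = np.nan
        out["t_rel50"] = np.nan
    else:
        for x in (10, 50):
            out[f"t_rel{x}"] = _first_crossing(
                time[i_min:], trace[i_min:], eps_min + 0.01 * x * span,
                downward=False)
    return out


def strain_rate(time: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Strain rate in %/s by central differences on the native grid."""
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        raise ValueError("trace shorter than 3 samples")
    return np.gradient(trace, time / 1000.0)


def strain_rate_indices(time: np.ndarray, trace: np.ndarray,
                        events: Mapping[str, float]) -> Dict[str, float]:
    """Peak and mean strain rate over the systolic and ejection windows."""
    time = np.asarray(time, dtype=float)
    sr = strain_rate(time, trace)
    t0, avo, avc = events["t0"], events["AVO"], events["AVC"]
    sys_mask = (time >= t0) & (time <= avc)
    ej_mask = (time >= avo) & (time <= avc)
    return {
        "sr_min_sys": float(sr[sys_mask].min()),
        "sr_min_ej": float(sr[ej_mask].min()),
        "mean_sr_sys": float(sr[sys_mask].mean()),
        "mean_sr_ej": float(sr[ej_mask].mean()),
    }


def volume_outputs(volume: np.ndarray) -> Tuple[float, float]:
    """EDV and SV (mL) of one full-cycle volume trace."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("non-positive cavity volume")
    edv = float(volume.max())
    return edv, edv - float(volume.min())


def output_vector(sim) -> Dict[str, float]:
    """All screening outputs of one simulation: EDV, SV and 16 indices
    per segment.  NaN-valued entries mark undefined timing indices."""
    edv, sv = volume_outputs(sim.volume)
    out = {"EDV": edv, "SV": sv}
    for i in range(sim.n_seg):
        si = strain_indices(sim.time, sim.strain[i], sim.events)
        ri = strain_rate_indices(sim.time, sim.strain[i], sim.events)
        for k, v in {**si, **ri}.items():
            out[f"seg{i + 1:02d}_{k}"] = v
    return out


def features_to_frame(sim):
    """Per-segment feature table (rows = segments, columns = 16 indices)."""
    import pandas as pd
    rows = []
    for i in range(sim.n_seg):
        row = {"segment": i + 1}
        row.update(strain_indices(sim.time, sim.strain[i], sim.events))
        row.update(strain_rate_indices(sim.time, sim.strain[i], sim.events))
        rows.append(row)
    return pd.DataFrame(rows).set_index("segment")
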