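"""Virtual-patient cohort generation and measurement file I/O.

Virtual patients emulate the strain morphologies and volumes of the
substrates of LV mechanical discoordination:

* ``healthy`` - homogeneous walls, simultaneous activation;
* ``LBBB-only`` - a graded mechanical activation delay oriented from the
  anterior septum towards the LV posterior wall (early septal, late
  lateral shortening onset);
* ``MI-only`` - a contiguous lesion with depressed contractility,
  reduced shortening velocity and raised passive stiffness, narrow-QRS
  activation;
* ``LBBB-MI`` - both substrates combined.

Measurements are exported at a configurable device sampling rate with
i.i.d. Gaussian noise per strain sample (sigma 2%) and one volume
perturbation per patient (relative sigmas 0.13 for EDV and 0.14 for EF,
the measurement-uncertainty factors of the cost function).  Measurement
CSVs carry ``time_ms, seg_01..seg_NN`` columns with a JSON sidecar for
volumes, cycle time and the segment scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import forward_model as fm
from .cost import MeasurementSet
from .registry import ParameterSubset, apply_segmentation, build_homogeneous_registry
from .work import region_map_18

ARCHETYPES = ("healthy", "LBBB-only", "MI-only", "LBBB-MI")

#: Wall order shared by the 6- and 18-segment schemes (see work.WALLS_18):
#: anteroseptal (S1), inferoseptal (S2), anterior, inferior,
#: inferolateral, anterolateral.  Activation travels anterior septum ->
#: posterior/lateral wall.
N_WALLS = 6
#: Walls carrying the infarct lesion (anteroseptal, anterior,
#: inferolateral): a contiguous arc of the LV circumference.
LESION_WALLS = (0, 2, 4)


@dataclass
class ActivationPattern:
    """LBBB-like mechanical activation timing.

    ``tau_sl`` is the total septal-to-lateral delay; ``tau_vv`` an
    interventricular offset added to every segment; the alpha/beta
    coefficients position the intermediately activated walls along the
    activation path.
    """

    tau_sl: float = 0.0
    tau_vv: float = 0.0
    alpha1: float = 0.15
    beta1: float = 0.35
    beta2: float = 0.60
    alpha2: float = 0.80

    def wall_positions(self) -> np.ndarray:
        return np.array([0.0, self.alpha1, self.beta1, self.beta2,
                         self.alpha2, 1.0])

    def segment_delays(self, n_seg: int) -> np.ndarray:
        """Per-segment mechanical activation delay dT (ms), >= 0."""
        per_wall = self.tau_vv + self.tau_sl * self.wall_positions()
        if n_seg == N_WALLS:
            d = per_wall
        elif n_seg == 3 * N_WALLS:
            d = np.repeat(per_wall, 3)
        else:
            raise ValueError(f"unsupported segment scheme {n_seg}")
        if np.any(d < 0):
            raise ValueError("negative activation delay")
        return d


@dataclass
class NoiseConfig:
    sigma_strain: float = 2.0     # %, per sample
    rel_sigma_edv: float = 0.13   # of the true EDV
    rel_sigma_ef: float = 0.14    # of the true EF
    level: float = 1.0            # overall multiplier (0 = noise-free)
    device_rate_hz: float = 60.0


@dataclass
class VirtualPatient:
    archetype: str
    seed: int
    truth: fm.ModelParameters
    measurement: MeasurementSet
    simulation: fm.SimulationResult = field(repr=False, default=None)

    @property
    def n_seg(self) -> int:
        return self.measurement.n_seg


def _segmented_registry(n_seg: int) -> ParameterSubset:
    return apply_segmentation(build_homogeneous_registry(), n_seg)


def _draw_truth(archetype: str, n_seg: int,
                rng: np.random.Generator) -> fm.ModelParameters:
    params = fm.reference_parameters(_segmented_registry(n_seg))
    params.scalars["q0"] = float(rng.uniform(55.0, 95.0))
    params.scalars["tCycle"] = float(rng.uniform(750.0, 950.0))
    if archetype in ("LBBB-only", "LBBB-MI"):
        pattern = ActivationPattern(tau_sl=float(rng.uniform(90.0, 130.0)))
        params.segmental["dT"] = pattern.segment_delays(n_seg)
    elif archetype == "MI-only":
        # narrow QRS: small non-directional activation scatter
        per_wall = rng.uniform(0.0, 15.0, size=N_WALLS)
        params.segmental["dT"] = (per_wall if n_seg == N_WALLS
                                  else np.repeat(per_wall, 3))
    if archetype in ("MI-only", "LBBB-MI"):
        seg_per_wall = n_seg // N_WALLS
        lesion = [w * seg_per_wall + k for w in LESION_WALLS
                  for k in range(seg_per_wall)]
        params.segmental["SfAct"][lesion] *= rng.uniform(0.25, 0.45)
        params.segmental["vMax"][lesion] *= rng.uniform(0.5, 0.8)
        params.segmental["k1"][lesion] *= rng.uniform(1.6, 2.4)
        params.segmental["SfPas"][lesion] *= rng.uniform(1.5, 2.5)
    return params


def export_measurement(sim: fm.SimulationResult, noise: NoiseConfig,
                       rng: np.random.Generator) -> MeasurementSet:
    """Resample a simulation to the device rate and add measurement noise."""
    from .features import volume_outputs

    t_cycle = float(sim.time[-1])
    step = 1000.0 / noise.device_rate_hz
    t = np.arange(0.0, t_cycle + 0.5 * step, step)
    t = t[t <= t_cycle]
    strain = np.vstack([np.interp(t, sim.time, s) for s in sim.strain])
    strain = strain + noise.level * noise.sigma_strain * \
        rng.standard_normal(strain.shape)
    edv, sv = volume_outputs(sim.volume)
    ef = 100.0 * sv / edv
    v_ed = edv * (1.0 + noise.level * noise.rel_sigma_edv
                  * rng.standard_normal())
    ef_mea = ef * (1.0 + noise.level * noise.rel_sigma_ef
                   * rng.standard_normal())
    return MeasurementSet(
        time=t, strain=strain,
        v_ed=float(np.clip(v_ed, 20.0, 600.0)),
        ef=float(np.clip(ef_mea, 5.0, 95.0)),
        t_cycle=t_cycle,
        meta={"scheme": sim.n_seg},
    )


def generate_patient(archetype: str, n_seg: int = 18, seed: int = 0,
                     noise: Optional[NoiseConfig] = None,
                     max_retries: int = 20) -> VirtualPatient:
    """Draw one virtual patient; regenerating with the same seed
    reproduces the measurement bitwise."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        truth = _draw_truth(archetype, n_seg, rng)
        sim = fm.simulate(truth)
        if sim.success:
            meas = export_measurement(sim, noise, rng)
            return VirtualPatient(archetype=archetype, seed=seed,
                                  truth=truth, measurement=meas,
                                  simulation=sim)
    raise RuntimeError(f"no successful simulation for {archetype} "
                       f"after {max_retries} draws")


def generate_cohort(counts: Dict[str, int], n_seg: int = 18, seed: int = 0,
                    noise: Optional[NoiseConfig] = None) -> List[VirtualPatient]:
    """A cohort with the given archetype counts (default study mix:
    4 LBBB-only / 6 MI-only / 3 LBBB-MI)."""
    patients = []
    k = 0
    for archetype, n in counts.items():
        for _ in range(n):
            patients.append(generate_patient(archetype, n_seg,
                                             seed=seed * 7919 + k, noise=noise))
            k += 1
    return patients


DEFAULT_COHORT = {"LBBB-only": 4, "MI-only": 6, "LBBB-MI": 3}


# ---------------------------------------------------------------------------
# Measurement I/O
# ---------------------------------------------------------------------------

def write_measurements(meas: MeasurementSet, csv_path, json_path=None) -> None:
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    cols = {"time_ms": meas.time}
    for i in range(meas.n_seg):
        cols[f"seg_{i + 1:02d}"] = meas.strain[i]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.17g")
    with open(json_path, "w") as fh:
        json.dump({
            "V_ED_mea_mL": meas.v_ed, "EF_mea_pct": meas.ef,
            "t_cycle_ms": meas.t_cycle, "scheme": meas.n_seg,
        }, fh, indent=2)


def read_measurements(csv_path, json_path=None) -> MeasurementSet:
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path else csv_path.with_suffix(".json")
    with open(json_path) as fh:
        sidecar = json.load(fh)
    for key in ("V_ED_mea_mL", "EF_mea_pct", "t_cycle_ms", "scheme"):
        if key not in sidecar:
            raise ValueError(f"missing sidecar field {key!r}")
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    seg_cols = [c for c in frame.columns if c.startswith("seg_")]
    if len(seg_cols) != int(sidecar["scheme"]):
        raise ValueError(
            f"{len(seg_cols)} strain columns but scheme declares "
            f"{sidecar['scheme']} segments")
    return MeasurementSet(
        time=frame["time_ms"].to_numpy(),
        strain=frame[seg_cols].to_numpy().T,
        v_ed=float(sidecar["V_ED_mea_mL"]), ef=float(sidecar["EF_mea_pct"]),
        t_cycle=float(sidecar["t_cycle_ms"]),
        meta={"scheme": int(sidecar["scheme"])},
    )


def average_apex_to_base(meas: MeasurementSet) -> MeasurementSet:
    """Average an 18-segment measurement to the 6-wall scheme (the
    apex/mid/base triplet of each wall collapses to its mean)."""
    if meas.n_seg != 18:
        raise ValueError("expects an 18-segment measurement")
    strain6 = meas.strain.reshape(6, 3, -1).mean(axis=1)
    return MeasurementSet(time=meas.time.copy(), strain=strain6,
                          v_ed=meas.v_ed, ef=meas.ef, t_cycle=meas.t_cycle,
                          meta={**meas.meta, "scheme": 6})


def wall_volumes(params: fm.ModelParameters) -> np.ndarray:
    """Segmental wall volumes (mL) for work indices."""
    return np.asarray(params.segmental["VWall"], dtype=float)


def region_labels(n_seg: int) -> Sequence[str]:
    if n_seg == 18:
        return region_map_18()
    if n_seg == 6:
        return ["S", "S", "other", "other", "LW", "LW"]
    raise ValueError(f"unsupported segment scheme {n_seg}")
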