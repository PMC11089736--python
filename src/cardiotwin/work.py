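"""Myocardial work indices from stress-strain loops.

Segmental myocardial work ``W_i`` is the area enclosed by the regional
stress-strain loop over one cycle multiplied by the segmental wall
volume; with stress in kPa, strain as a fraction and volume in mL the
product is in mJ.  Normalized work divides by the summed work of all
segments, and the septal-to-lateral workload imbalance is

    dW_norm,LW-S = sum(W_norm over 6 posterolateral segments)
                 - sum(W_norm over 6 septal segments),

positive when the lateral wall performs more work than the septum (the
typical left-bundle-branch-block pattern).
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd

#: Wall order of the 18-segment scheme (three segments per wall,
#: apex/mid/base).  The septal region S comprises the anteroseptal and
#: inferoseptal walls, the posterolateral region LW the inferolateral
#: and anterolateral walls; the anterior and inferior walls are the
#: six remaining ("other") segments.
WALLS_18 = (
    ("anteroseptal", "S"),
    ("inferoseptal", "S"),
    ("anterior", "other"),
    ("inferior", "other"),
    ("inferolateral", "LW"),
    ("anterolateral", "LW"),
)


def region_map_18() -> list:
    """Region label per segment of the 18-segment scheme."""
    return [region for _, region in WALLS_18 for _ in range(3)]


def loop_area(x: np.ndarray, y: np.ndarray) -> float:
    """Signed shoelace area of the closed polygon (x, y).

    The endpoints are joined; the area is invariant to cyclic rotation
    of the start index, and a figure-eight contributes its net signed
    area.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("traces of unequal length")
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def segment_work(strain_frac: np.ndarray, stress_kpa: np.ndarray,
                 wall_volume_ml: float) -> float:
    """Work of one segment (mJ-equivalent, kPa * mL).

    ``W = -∮ sigma d(eps) * V_wall``: shortening at high tension with
    re-lengthening at low tension traverses the (strain, stress) plane
    counterclockwise, so work-performing loops have positive shoelace
    area and positive work.
    """
    return loop_area(strain_frac, stress_kpa) * wall_volume_ml


def work_per_segment(sim, wall_volumes: np.ndarray) -> np.ndarray:
    """Segmental work vector of one simulation (strain % -> fraction)."""
    wall_volumes = np.asarray(wall_volumes, dtype=float)
    if wall_volumes.size != sim.n_seg:
        raise ValueError("wall volume per segment required")
    return np.array([
        segment_work(sim.strain[i] / 100.0, sim.stress[i], wall_volumes[i])
        for i in range(sim.n_seg)
    ])


def normalized_work(w: np.ndarray) -> np.ndarray:
    """W_norm,i = W_i / sum_j W_j (requires nonzero total)."""
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total == 0.0:
        raise ValueError("zero total work")
    return w / total


def workload_imbalance(w_norm: np.ndarray, region_map: Sequence[str]) -> float:
    """Summed normalized work of LW segments minus that of S segments."""
    w_norm = np.asarray(w_norm, dtype=float)
    labels = list(region_map)
    if len(labels) != w_norm.size:
        raise ValueError("region map does not match segment count")
    lw = [i for i, r in enumerate(labels) if r == "LW"]
    s = [i for i, r in enumerate(labels) if r == "S"]
    if not lw or not s:
        raise ValueError("region map must contain LW and S segments")
    if w_norm.size == 18 and (len(lw) != 6 or len(s) != 6):
        raise ValueError("18-segment map must have 6 LW and 6 S segments")
    return float(w_norm[lw].sum() - w_norm[s].sum())


def work_summary(sim, wall_volumes: np.ndarray,
                 region_map: Sequence[str]) -> Dict[str, object]:
    """Per-segment work table plus the imbalance index of one twin."""
    w = work_per_segment(sim, wall_volumes)
    wn = normalized_work(w)
    frame = pd.DataFrame({
        "segment": np.arange(1, sim.n_seg + 1),
        "W_mJ": w, "W_norm": wn, "region": list(region_map),
    }).set_index("segment")
    return {
        "table": frame,
        "dW_norm_LW_S": workload_imbalance(wn, region_map),
    }
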