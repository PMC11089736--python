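"""Reproducibility of repeated parameter estimations via the ICC.

The one-way random-effects intraclass correlation coefficient of an
``n x m`` matrix (n subjects, m repeated observations) is

    ICC = (MS_between - MS_within) / (MS_between + (m - 1) * MS_within)

with the classical mean squares

    MS_between = m * sum_i (S_i - xbar)^2 / (n - 1)
    MS_within  = sum_ij (x_ij - S_i)^2 / (n * (m - 1)).

For a regional LV parameter the subjects are every (patient, segment)
pair; for a global parameter the subjects are the patients.  A subset is
accepted when the minimum ICC over its parameter groups exceeds 0.75
(good reproducibility); the inequality is strict.

Parameters whose sampling range spans more than one decade are
log-transformed before the mean squares are formed, since the ICC is
scale-sensitive; the transform is recorded per group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .registry import ParameterSubset

ICC_THRESHOLD = 0.75


def icc(data: np.ndarray) -> float:
    """One-way random-effects ICC of an n x m matrix (no missing cells).

    Degenerate matrices with zero total variance are perfectly
    reproducible (ICC = 1); if only the denominator vanishes the value
    is undefined and returned as NaN.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ICC needs an n x m matrix with n >= 2, m >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells in ICC matrix")
    n, m = x.shape
    subj = x.mean(axis=1)
    grand = x.mean()
    ms_between = m * ((subj - grand) ** 2).sum() / (n - 1)
    ms_within = ((x - subj[:, None]) ** 2).sum() / (n * (m - 1))
    denom = ms_between + (m - 1) * ms_within
    if denom == 0.0:
        return 1.0 if ms_within == 0.0 else np.nan
    return float((ms_between - ms_within) / denom)


def subject_count(scope: str, n_patients: int, n_seg: int) -> int:
    """Number of ICC subjects for a parameter group.

    Regional groups pool segments across patients (n = segments x
    patients); global and global-offset parameters use the patients.
    """
    if scope == "regional":
        return n_seg * n_patients
    return n_patients


def needs_log_transform(lo: float, hi: float) -> bool:
    """Log-transform rule: all-positive range spanning > 1 decade."""
    return lo > 0 and hi / lo > 10.0


@dataclass
class ICCTable:
    """Per-group ICC with subject/observation counts."""

    table: pd.DataFrame  # index: group; columns: icc, n, m, log_transformed

    @property
    def icc_min(self) -> float:
        return float(self.table["icc"].min())

    def accept(self) -> bool:
        """Reproducibility gate: strict ICC_min > 0.75."""
        return bool(self.icc_min > ICC_THRESHOLD)

    def lowest_group(self) -> str:
        return str(self.table["icc"].idxmin())


def icc_table(estimates: Mapping[str, np.ndarray],
              subset: Optional[ParameterSubset] = None) -> ICCTable:
    """ICC per parameter group.

    ``estimates[group]`` is the n x m matrix of estimated values
    (subjects x repeats).  When the subset is given, each group's
    sampling range decides the log-transform.
    """
    rows = {}
    for group, mat in estimates.items():
        mat = np.asarray(mat, dtype=float)
        logged = False
        if subset is not None and subset.has_group(group):
            spec = next(s for s in subset.specs if s.name == group)
            if needs_log_transform(*spec.msm_range) and np.all(mat > 0):
                mat = np.log(mat)
                logged = True
        rows[group] = {
            "icc": icc(mat), "n": mat.shape[0], "m": mat.shape[1],
            "log_transformed": logged,
        }
    return ICCTable(table=pd.DataFrame(rows).T)
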