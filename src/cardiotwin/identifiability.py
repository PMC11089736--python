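"""Sample-based parameter identifiability via diaphony.

A Sobol low-discrepancy sample of the normalized parameter space is
scored against each patient's measurements with the identifiability cost
(total and each individual component).  For every score component the
best ``N_best = 2 * n_par`` samples are selected, and the diaphony of
each parameter's normalized values over that selection,

    d_p = | mean over selected samples of exp(i * 2*pi * x_p) |,

measures on a 0-to-1 scale how strongly the component pins the
parameter: values near 1 mean the selected samples cluster at a
preferred value (identifiable), values near 0 mean they spread over the
range.  Parameters are ranked by their maximum diaphony over all
patients and components; for a regional parameter the maximum over its
segments is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc


def sobol_sample(n_dim: int, n: int, seed: Optional[int] = None,
                 scramble: bool = True) -> np.ndarray:
    """Scrambled Sobol points in [0,1]^D, deterministic per seed.

    ``n`` is rounded up to the next power of two to preserve the
    sequence's balance properties.
    """
    sampler = qmc.Sobol(d=n_dim, scramble=scramble, seed=seed)
    m = int(np.ceil(np.log2(max(n, 1))))
    pts = sampler.random_base2(m) if m > 0 else sampler.random(1)
    return pts[:n]


def map_to_ranges(unit: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Affine map of unit-cube samples onto the sampling ranges."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    return lo + unit * (hi - lo)


def select_best(scores: np.ndarray, n_best: int) -> np.ndarray:
    """Indices of the ``n_best`` lowest finite scores.

    Non-finite scores (failed simulations) are excluded; ties are broken
    by sample index (stable sort).
    """
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    if finite.sum() < n_best:
        raise ValueError(
            f"only {int(finite.sum())} successful samples, need {n_best}")
    idx = np.flatnonzero(finite)
    order = idx[np.argsort(scores[finite], kind="stable")]
    return order[:n_best]


def diaphony(x: np.ndarray) -> float:
    """|mean unit phasor| of normalized samples x in [0,1]."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty selection")
    return float(np.abs(np.exp(2j * np.pi * x).mean()))


@dataclass
class DiaphonyTable:
    """Diaphony per (parameter, component, dataset) with group ranking."""

    table: pd.DataFrame      # index: parameter key; columns: (dataset, component)
    n_best: int
    groups: Mapping[str, Sequence[str]]  # group name -> parameter keys

    def group_max(self) -> pd.Series:
        """Max diaphony per parameter group over datasets, components
        and (for regional groups) segments."""
        per_param = self.table.max(axis=1)
        return pd.Series(
            {g: float(per_param.loc[list(keys)].max())
             for g, keys in self.groups.items()}
        ).sort_values()

    def rank_parameters(self) -> List[str]:
        """Group names in ascending max-diaphony order (least
        identifiable first)."""
        return list(self.group_max().index)


def diaphony_table(
    samples_unit: np.ndarray,
    component_scores: Mapping[str, Mapping[str, np.ndarray]],
    param_keys: Sequence[str],
    groups: Mapping[str, Sequence[str]],
    n_best: Optional[int] = None,
) -> DiaphonyTable:
    """Build the diaphony table from scored Sobol samples.

    ``component_scores[dataset][component]`` is an array of per-sample
    scores (NaN/inf = failed); ``samples_unit`` has one column per entry
    of ``param_keys``.  ``n_best`` defaults to twice the number of
    parameters.
    """
    n_par = len(param_keys)
    if n_best is None:
        n_best = 2 * n_par
    cols = {}
    for ds, comps in component_scores.items():
        for comp, scores in comps.items():
            sel = select_best(scores, n_best)
            sub = samples_unit[sel]
            cols[(ds, comp)] = [diaphony(sub[:, j]) for j in range(n_par)]
    table = pd.DataFrame(cols, index=list(param_keys))
    return DiaphonyTable(table=table, n_best=n_best, groups=groups)
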