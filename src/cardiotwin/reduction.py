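"""Iterative parameter-subset reduction.

The outer loop alternates repeated estimation (reproducibility), ICC
gating, and diaphony-based identifiability ranking:

1. estimate the current subset on every cohort member with repeated
   DMS-PSO runs;
2. accept the subset when the minimum ICC over parameter groups exceeds
   0.75, otherwise
3. rank groups by Sobol-sample diaphony (cycle time added as an
   auxiliary sampling dimension so one simulation set covers all
   patients), and
4. remove groups: 10 / 5 / 3 at a time while more than 30 / 16-30 /
   11-15 groups remain; with 10 or fewer groups a single group is
   removed per iteration, choosing between the lowest-diaphony and
   lowest-ICC candidates by whichever causes the smallest maximal
   chi-square increase across the cohort.

A removed regional LV group returns as a single global-offset
parameter; removed global parameters are fixed to their reference
values, so no parameter silently disappears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import cost as cost_mod
from . import estimation as est
from . import forward_model as fm
from . import identifiability as ident
from . import reproducibility as repro
from .cohort import VirtualPatient, average_apex_to_base
from .registry import ParameterSubset, demote_to_global_offset

logger = logging.getLogger(__name__)


def removal_count(n_groups: int) -> int:
    """How many parameter groups one iteration removes."""
    if n_groups < 1:
        raise ValueError("subset has no groups")
    if n_groups > 30:
        return 10
    if n_groups >= 16:
        return 5
    if n_groups >= 11:
        return 3
    return 1


@dataclass
class ReductionConfig:
    swarm: est.SwarmConfig = field(default_factory=est.SwarmConfig)
    cost: cost_mod.CostConfig = field(default_factory=cost_mod.CostConfig)
    sobol_n: int = 2 ** 16
    candidate_repeats: int = 1
    include_tcycle: bool = True
    max_iterations: int = 50
    seed: int = 0


@dataclass
class ReductionState:
    subset: ParameterSubset
    log: List[dict] = field(default_factory=list)
    decisions: List[dict] = field(default_factory=list)

    def trace_frame(self):
        import pandas as pd
        return pd.DataFrame(self.log)


def _group_estimates(subset: ParameterSubset,
                     all_results: Sequence[Sequence[est.EstimationResult]],
                     space_keys: Sequence[str]) -> Dict[str, np.ndarray]:
    """Estimate matrices (subjects x repeats) per parameter group."""
    key_index = {k: i for i, k in enumerate(space_keys)}
    out: Dict[str, np.ndarray] = {}
    for group, specs in subset.groups().items():
        rows = []
        for per_patient in all_results:
            for spec in specs:
                key = spec.name if spec.segment_index is None \
                    else f"{spec.name}[{spec.segment_index}]"
                j = key_index[key]
                rows.append([r.best_x[j] for r in per_patient])
        out[group] = np.array(rows)
    return out


def _identifiability_scores(subset: ParameterSubset,
                            base_params: fm.ModelParameters,
                            patients: Sequence[VirtualPatient],
                            cfg: ReductionConfig,
                            rng_seed: int):
    """Sobol-sampled component scores per patient for the current subset."""
    specs = list(subset.specs)
    keys = [s.name if s.segment_index is None else f"{s.name}[{s.segment_index}]"
            for s in specs]
    lo = np.array([s.msm_range[0] for s in specs])
    hi = np.array([s.msm_range[1] for s in specs])
    has_tcycle = any(s.name == "tCycle" for s in specs)
    if cfg.include_tcycle and not has_tcycle:
        keys = keys + ["tCycle"]
        t_meas = [p.measurement.t_cycle for p in patients]
        lo = np.append(lo, min(t_meas) - 100.0)
        hi = np.append(hi, max(t_meas) + 100.0)

    unit = ident.sobol_sample(len(keys), cfg.sobol_n, seed=rng_seed)
    phys = ident.map_to_ranges(unit, lo, hi)

    space = est.ParameterSpace(subset, base_params)
    measurements = []
    for p in patients:
        m = p.measurement
        measurements.append(average_apex_to_base(m) if m.n_seg == 18
                            and subset.n_seg == 6 else m)
    n_seg = measurements[0].n_seg
    contexts = [cost_mod.CostContext(m, cfg.cost) for m in measurements]

    comp_names = (["chi2_IA", "chi2_VED", "chi2_EF", "chi2_tcycle"]
                  + [f"chi2_eps_seg{i}" for i in range(n_seg)]
                  + [f"chi2_epsdot_seg{i}" for i in range(n_seg)])
    scores = {s: {c: np.full(cfg.sobol_n, np.nan) for c in comp_names}
              for s in range(len(patients))}

    for k in range(cfg.sobol_n):
        vec = phys[k, :space.n_dim]
        params = space.to_params(vec)
        if cfg.include_tcycle and not has_tcycle:
            params.scalars["tCycle"] = float(phys[k, -1])
        sim = fm.simulate(params)
        if not sim.success:
            continue
        t_mod = params.scalars["tCycle"]
        for s, meas in enumerate(measurements):
            try:
                comps = contexts[s].components(sim)
            except ValueError:
                continue
            ct = cost_mod.chi2_tcycle_term(t_mod, meas.t_cycle, cfg.cost)
            scores[s]["chi2_IA"][k] = cost_mod.chi2_ia(comps, ct, n_seg)
            scores[s]["chi2_VED"][k] = comps["chi2_VED"]
            scores[s]["chi2_EF"][k] = comps["chi2_EF"]
            scores[s]["chi2_tcycle"][k] = ct
            for i in range(n_seg):
                scores[s][f"chi2_eps_seg{i}"][k] = comps["chi2_eps_seg"][i]
                scores[s][f"chi2_epsdot_seg{i}"][k] = comps["chi2_epsdot_seg"][i]

    groups = {g: [k for k, spec in zip(keys[:space.n_dim], specs)
                  if spec.name == g]
              for g in subset.groups()}
    n_par = space.n_dim
    return ident.diaphony_table(unit, scores, keys, groups,
                                n_best=2 * n_par)


def _estimate_cohort(subset: ParameterSubset, base_params: fm.ModelParameters,
                     patients: Sequence[VirtualPatient],
                     cfg: ReductionConfig, seed: int, repeats: int):
    """Repeated estimation per patient; returns results and chi2 stats."""
    swarm = est.SwarmConfig(**{**cfg.swarm.__dict__, "repeats": repeats})
    all_results = []
    for i, p in enumerate(patients):
        meas = p.measurement
        if meas.n_seg == 18 and subset.n_seg == 6:
            meas = average_apex_to_base(meas)
        res = est.repeated_estimation(meas, subset, base_params, swarm,
                                      seed=seed * 10_007 + i,
                                      cost_cfg=cfg.cost)
        all_results.append(res)
    best_chi2 = np.array([min(r.best_chi2 for r in res) for res in all_results])
    return all_results, best_chi2


def propose_and_choose(state: ReductionState, ranking: List[str],
                       icc_tab: repro.ICCTable,
                       patients: Sequence[VirtualPatient],
                       base_params: fm.ModelParameters,
                       cfg: ReductionConfig, baseline_chi2: np.ndarray,
                       iteration: int) -> ReductionState:
    """One Step-2d removal applied to the current subset."""
    subset = state.subset
    n_groups = len(subset.groups())
    k = removal_count(n_groups)
    if n_groups > 10:
        removed = ranking[:k]
        new_subset = subset
        for g in removed:
            new_subset = demote_to_global_offset(new_subset, g)
        state.decisions.append({
            "iteration": iteration, "mode": "diaphony",
            "removed": removed,
        })
        return ReductionState(new_subset, state.log, state.decisions)

    cand_d = ranking[0]
    cand_icc = icc_tab.lowest_group()
    if cand_d == cand_icc:
        chosen, detail = cand_d, {"single_candidate": True}
    else:
        deltas = {}
        for cand in (cand_d, cand_icc):
            trial = demote_to_global_offset(subset, cand)
            _, chi2_trial = _estimate_cohort(
                trial, base_params, patients, cfg,
                seed=cfg.seed * 31 + iteration * 7 + sum(map(ord, cand)) % 1000,
                repeats=cfg.candidate_repeats)
            deltas[cand] = float(np.max(chi2_trial - baseline_chi2))
        chosen = min(deltas, key=deltas.get)
        detail = {"delta_chi2_max": deltas}
    new_subset = demote_to_global_offset(subset, chosen)
    state.decisions.append({
        "iteration": iteration, "mode": "dual-candidate",
        "candidates": [cand_d, cand_icc], "removed": [chosen], **detail,
    })
    return ReductionState(new_subset, state.log, state.decisions)


def reduction_loop(subset: ParameterSubset,
                   patients: Sequence[VirtualPatient],
                   base_params: Optional[fm.ModelParameters] = None,
                   cfg: Optional[ReductionConfig] = None) -> ReductionState:
    """Run Steps 2a-2d until the reproducibility gate passes.

    Emits a per-iteration trace of subset size, ICC_min and the cohort
    mean and SD of the best chi-square.
    """
    cfg = cfg or ReductionConfig()
    if base_params is None:
        from .registry import apply_segmentation, build_homogeneous_registry
        base_params = fm.reference_parameters(
            apply_segmentation(build_homogeneous_registry(), subset.n_seg))
    state = ReductionState(subset)
    for iteration in range(cfg.max_iterations):
        groups = state.subset.groups()
        results, best_chi2 = _estimate_cohort(
            state.subset, base_params, patients, cfg,
            seed=cfg.seed + 1000 * iteration, repeats=cfg.swarm.repeats)
        keys = est.ParameterSpace(state.subset, base_params).keys
        estimates = _group_estimates(state.subset, results, keys)
        icc_tab = repro.icc_table(estimates, state.subset)
        state.log.append({
            "iteration": iteration, "size": state.subset.size,
            "n_groups": len(groups), "icc_min": icc_tab.icc_min,
            "chi2_mean": float(best_chi2.mean()),
            "chi2_sd": float(best_chi2.std()),
        })
        logger.info("iteration %d: size=%d groups=%d ICC_min=%.3f "
                    "chi2=%.3f+-%.3f", iteration, state.subset.size,
                    len(groups), icc_tab.icc_min, best_chi2.mean(),
                    best_chi2.std())
        if icc_tab.accept():
            state.decisions.append({"iteration": iteration, "mode": "accept",
                                    "icc_min": icc_tab.icc_min})
            return state
        if len(groups) <= 1:
            state.decisions.append({"iteration": iteration,
                                    "mode": "floor-reached",
                                    "icc_min": icc_tab.icc_min})
            return state
        dia = _identifiability_scores(state.subset, base_params, patients,
                                      cfg, rng_seed=cfg.seed + iteration)
        ranking = dia.rank_parameters()
        state = propose_and_choose(state, ranking, icc_tab, patients,
                                   base_params, cfg, best_chi2, iteration)
    raise RuntimeError("reduction loop exceeded max_iterations")
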