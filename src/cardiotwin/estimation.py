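"""Parameter estimation: Monte-Carlo seeding + dynamic multi-swarm PSO.

Each estimation run draws a pool of Monte-Carlo samples uniformly from
the screening ranges (with configurable physiological restrictions on
dyssynchrony severity, global contractility and stiffness), evaluates
the cost for each, and seeds the swarm with the best samples.  The
swarm is split into many small swarms (default 20 swarms of 3
particles) that are randomly regrouped every 20 iterations to maintain
diversity.  Particle updates use the standard constriction
coefficients (inertia 0.729, cognitive = social = 1.49445); velocities
are clamped to 25% of the extended input-space width per dimension, and
the cost is infinite outside the extended boundaries.

The run stops when normalized particle energies fall below 1e-4 - no
parameter of any particle moved more than 1% of its Monte-Carlo range
width within one iteration and the mean-square normalized displacement
is below 1e-4 - or after the iteration budget.  Repeated estimations
with independent seeds supply the observations for reproducibility
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import cost as cost_mod
from . import forward_model as fm
from .registry import ParameterSubset


@dataclass
class SwarmConfig:
    particles: int = 60
    n_swarms: int = 20
    regroup_every: int = 20
    velocity_frac: float = 0.25     # of extended input-space width
    energy_tol: float = 1e-4        # mean-square normalized displacement
    max_step_frac: float = 0.01     # max |dx| per MC-range width
    max_iter: int = 2000
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    mc_pool: int = 1000
    mc_reject_budget: int = 100     # resampling factor for constraints
    repeats: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.particles % self.n_swarms:
            raise ValueError("particles must be divisible by n_swarms")


class ParameterSpace:
    """Vector view of an estimation subset.

    Fixes the coordinate order (the subset's spec order), exposes the
    screening (MC) ranges and extended swarm bounds per coordinate, and
    materializes :class:`~cardiotwin.forward_model.ModelParameters` from
    vectors.
    """

    def __init__(self, subset: ParameterSubset,
                 base_params: fm.ModelParameters) -> None:
        self.subset = subset
        self.base = base_params
        self.specs = list(subset.specs)
        self.keys = [
            s.name if s.segment_index is None else f"{s.name}[{s.segment_index}]"
            for s in self.specs
        ]
        self.mc_lo = np.array([s.msm_range[0] for s in self.specs])
        self.mc_hi = np.array([s.msm_range[1] for s in self.specs])
        self.pso_lo = np.array([s.pso_bounds[0] for s in self.specs])
        self.pso_hi = np.array([s.pso_bounds[1] for s in self.specs])

    @property
    def n_dim(self) -> int:
        return len(self.specs)

    @property
    def mc_width(self) -> np.ndarray:
        return self.mc_hi - self.mc_lo

    @property
    def pso_width(self) -> np.ndarray:
        return self.pso_hi - self.pso_lo

    def to_params(self, vec: np.ndarray) -> fm.ModelParameters:
        params = self.base.copy()
        for value, spec in zip(vec, self.specs):
            if spec.scope == "regional":
                params.segmental[spec.name][spec.segment_index] = float(value)
            else:
                params.scalars[spec.name] = float(value)
        return params

    def as_dict(self, vec: np.ndarray) -> Dict[str, float]:
        return dict(zip(self.keys, map(float, vec)))


def make_objective(space: ParameterSpace, meas: cost_mod.MeasurementSet,
                   cfg: Optional[cost_mod.CostConfig] = None
                   ) -> Callable[[np.ndarray], float]:
    """chi2 objective over the subset's vector space.

    Infinite outside the extended boundaries and for failed simulations.
    The model cycle time is pinned to the measured cycle time unless
    ``tCycle`` is itself part of the subset.
    """
    base = space.base.copy()
    if "tCycle" not in {s.name for s in space.specs}:
        base.scalars["tCycle"] = float(meas.t_cycle)
    inner_space = ParameterSpace(space.subset, base)
    ctx = cost_mod.CostContext(meas, cfg)

    def objective(vec: np.ndarray) -> float:
        vec = np.asarray(vec, dtype=float)
        if np.any(vec < space.pso_lo) or np.any(vec > space.pso_hi):
            return np.inf
        return ctx.chi2(fm.simulate(inner_space.to_params(vec)))

    return objective


# ---------------------------------------------------------------------------
# Monte-Carlo initialization
# ---------------------------------------------------------------------------

def default_constraints(space: ParameterSpace) -> List[Callable[[np.ndarray], bool]]:
    """Physiological restrictions on Monte-Carlo draws.

    Defaults bound the spread of mechanical activation delays (<= 130
    ms), mean segmental contractility (SfAct in [40, 150] kPa) and mean
    stiffness (k1 <= 32) whenever those parameters are sampled.
    """
    dt_idx = [i for i, s in enumerate(space.specs) if s.name == "dT"]
    sfact_idx = [i for i, s in enumerate(space.specs) if s.name == "SfAct"]
    k1_idx = [i for i, s in enumerate(space.specs) if s.name == "k1"]
    cons: List[Callable[[np.ndarray], bool]] = []
    if len(dt_idx) >= 2:
        cons.append(lambda v: v[dt_idx].max() - v[dt_idx].min() <= 130.0)
    if sfact_idx:
        cons.append(lambda v: 40.0 <= v[sfact_idx].mean() <= 150.0)
    if k1_idx:
        cons.append(lambda v: v[k1_idx].mean() <= 32.0)
    return cons


def mc_initialize(space: ParameterSpace, objective: Callable[[np.ndarray], float],
                  cfg: SwarmConfig, rng: np.random.Generator,
                  constraints: Optional[Sequence[Callable]] = None
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Evaluate a constrained uniform Monte-Carlo pool and return the
    best ``particles`` positions and their costs."""
    if constraints is None:
        constraints = default_constraints(space)
    pool = []
    budget = cfg.mc_reject_budget * cfg.mc_pool
    tried = 0
    while len(pool) < cfg.mc_pool and tried < budget:
        tried += 1
        v = rng.uniform(space.mc_lo, space.mc_hi)
        if all(c(v) for c in constraints):
            pool.append(v)
    if len(pool) < cfg.mc_pool:
        raise RuntimeError("Monte-Carlo constraints too restrictive")
    pool_arr = np.array(pool)
    costs = np.array([objective(v) for v in pool_arr])
    ok = np.isfinite(costs)
    if ok.sum() < cfg.particles:
        raise RuntimeError(
            f"only {int(ok.sum())} successful Monte-Carlo samples, "
            f"need {cfg.particles}")
    order = np.flatnonzero(ok)[np.argsort(costs[ok], kind="stable")]
    best = order[:cfg.particles]
    return pool_arr[best], costs[best]


# ---------------------------------------------------------------------------
# Dynamic multi-swarm PSO
# ---------------------------------------------------------------------------

@dataclass
class EstimationResult:
    best_x: np.ndarray
    best_chi2: float
    n_iter: int
    termination: str
    history: np.ndarray = field(default_factory=lambda: np.empty(0))
    mc_best_chi2: float = np.nan
    keys: Sequence[str] = ()

    def as_dict(self) -> dict:
        return {
            "best": {k: float(v) for k, v in zip(self.keys, self.best_x)},
            "chi2": float(self.best_chi2),
            "iterations": int(self.n_iter),
            "termination": self.termination,
        }


def dms_pso(initial_positions: np.ndarray,
            objective: Callable[[np.ndarray], float],
            space: ParameterSpace, cfg: SwarmConfig,
            rng: np.random.Generator,
            initial_costs: Optional[np.ndarray] = None) -> EstimationResult:
    """Dynamic multi-swarm particle swarm optimization."""
    x = np.array(initial_positions, dtype=float)
    n_part, n_dim = x.shape
    if n_part != cfg.particles:
        raise ValueError("initial positions do not match particle count")
    v = np.zeros_like(x)
    vmax = cfg.velocity_frac * space.pso_width
    mc_w = np.maximum(space.mc_width, 1e-300)

    if initial_costs is None:
        f = np.array([objective(xi) for xi in x])
    else:
        f = np.array(initial_costs, dtype=float)
    if not np.any(np.isfinite(f)):
        raise RuntimeError("objective infinite for every initial particle")
    pbest_x = x.copy()
    pbest_f = f.copy()
    gi = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[gi].copy(), float(pbest_f[gi])
    mc_best = gbest_f

    swarm_of = np.repeat(np.arange(cfg.n_swarms), n_part // cfg.n_swarms)
    history = []
    termination = "max_iter"
    it = 0
    for it in range(1, cfg.max_iter + 1):
        if cfg.regroup_every and it % cfg.regroup_every == 0:
            swarm_of = swarm_of[rng.permutation(n_part)]
        # local best per swarm from personal bests
        lbest_x = np.empty_like(x)
        for s in range(cfg.n_swarms):
            members = np.flatnonzero(swarm_of == s)
            li = members[int(np.argmin(pbest_f[members]))]
            lbest_x[members] = pbest_x[li]
        r1 = rng.random((n_part, n_dim))
        r2 = rng.random((n_part, n_dim))
        v = (cfg.inertia * v
             + cfg.cognitive * r1 * (pbest_x - x)
             + cfg.social * r2 * (lbest_x - x))
        np.clip(v, -vmax, vmax, out=v)
        x = x + v
        f = np.array([objective(xi) for xi in x])
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        gi = int(np.argmin(pbest_f))
        if pbest_f[gi] < gbest_f:
            gbest_f = float(pbest_f[gi])
            gbest_x = pbest_x[gi].copy()
        history.append(gbest_f)
        step = np.abs(v) / mc_w
        if step.max() < cfg.max_step_frac and (step ** 2).mean() < cfg.energy_tol:
            termination = "energy"
            break
    return EstimationResult(
        best_x=gbest_x, best_chi2=gbest_f, n_iter=it, termination=termination,
        history=np.asarray(history), mc_best_chi2=mc_best, keys=space.keys)


def estimate(meas: cost_mod.MeasurementSet, subset: ParameterSubset,
             base_params: fm.ModelParameters, cfg: SwarmConfig,
             seed: Optional[int] = None,
             cost_cfg: Optional[cost_mod.CostConfig] = None,
             constraints: Optional[Sequence[Callable]] = None
             ) -> EstimationResult:
    """One full estimation run: MC seeding followed by DMS-PSO."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    space = ParameterSpace(subset, base_params)
    objective = make_objective(space, meas, cost_cfg)
    x0, f0 = mc_initialize(space, objective, cfg, rng, constraints)
    return dms_pso(x0, objective, space, cfg, rng, initial_costs=f0)


def repeated_estimation(meas: cost_mod.MeasurementSet, subset: ParameterSubset,
                        base_params: fm.ModelParameters, cfg: SwarmConfig,
                        seed: Optional[int] = None,
                        cost_cfg: Optional[cost_mod.CostConfig] = None
                        ) -> List[EstimationResult]:
    """Independent repeated estimations (default 5) with distinct seeds.

    Runs are seeded from a single seed sequence, so results are
    identical whether executed serially or in parallel.
    """
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    results = []
    for child in root.spawn(cfg.repeats):
        rng = np.random.default_rng(child)
        space = ParameterSpace(subset, base_params)
        objective = make_objective(space, meas, cost_cfg)
        x0, f0 = mc_initialize(space, objective, cfg, rng)
        results.append(dms_pso(x0, objective, space, cfg, rng, initial_costs=f0))
    return results
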