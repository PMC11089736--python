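"""Morris elementary-effects screening.

The normalized D-dimensional input space is discretized into a z-level
grid (default z = 8) with values {0, 1/(z-1), ..., 1}.  A trajectory
starts at a random grid point and changes one parameter at a time, in
random order, by the step Delta = (1/2) * z/(z-1) taken in whichever
direction stays inside [0, 1]; with this step size every grid point is
equally likely to be visited.  Each pair of consecutive points yields
one elementary effect per output,

    EE_i = (Y(x + Delta*e_i) - Y(x)) / (signed Delta),

and mu* is the mean absolute elementary effect across trajectories.
Any failed model evaluation voids the whole trajectory.

Importance: per output, mu* is normalized by the across-parameter mean;
a parameter is kept iff its normalized mu* is >= 1 for at least one
output.  Convergence of this classification is verified by leave-one-out
cross-validation over trajectories; if the trajectory budget is
exhausted before convergence, a bootstrap percentile confidence interval
decides (a parameter is non-important for an output only when the whole
95% CI of mu* lies below the across-parameter mean).

Screening iterates: parameters removed (fixed at their reference
position) are dropped from the active space, and the procedure repeats
until every remaining parameter is important for some output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class MorrisConfig:
    z: int = 8                 # grid levels (even)
    min_traj: int = 1000       # successful trajectories before first check
    batch: int = 100           # additional trajectories per convergence check
    max_traj: int = 3000       # budget; bootstrap CI path beyond this
    n_boot: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.z < 2 or self.z % 2:
            raise ValueError("z must be even and >= 2")

    @property
    def delta(self) -> float:
        return 0.5 * self.z / (self.z - 1)


@dataclass
class Trajectory:
    points: np.ndarray        # (D+1, D) in [0,1]
    order: np.ndarray         # (D,) parameter index changed at each step
    signed_delta: np.ndarray  # (D,) signed step of each change


@dataclass
class MorrisResult:
    mu_star: np.ndarray            # (D, n_out)
    n_traj: int
    ci_lower: Optional[np.ndarray] = None   # (D, n_out) bootstrap 95% CI
    ci_upper: Optional[np.ndarray] = None
    important: Optional[np.ndarray] = None  # (D,) bool
    outputs: Optional[Sequence[str]] = None


def build_trajectory(n_dim: int, cfg: MorrisConfig,
                     rng: np.random.Generator) -> Trajectory:
    """One random one-at-a-time trajectory of D+1 grid points."""
    z, delta = cfg.z, cfg.delta
    levels = np.arange(z) / (z - 1)
    x = levels[rng.integers(0, z, size=n_dim)].copy()
    order = rng.permutation(n_dim)
    points = np.empty((n_dim + 1, n_dim))
    points[0] = x
    signed = np.empty(n_dim)
    for k, i in enumerate(order):
        up_ok = x[i] + delta <= 1.0 + 1e-12
        dn_ok = x[i] - delta >= -1e-12
        if up_ok and dn_ok:
            step = delta if rng.random() < 0.5 else -delta
        elif up_ok:
            step = delta
        elif dn_ok:
            step = -delta
        else:  # pragma: no cover - impossible for delta <= 1
            raise AssertionError("no feasible Morris step")
        x = x.copy()
        x[i] = min(max(x[i] + step, 0.0), 1.0)
        signed[k] = step
        points[k + 1] = x
    return Trajectory(points=points, order=order, signed_delta=signed)


def elementary_effects(traj: Trajectory, outputs: np.ndarray) -> np.ndarray:
    """Per-parameter elementary effects of one trajectory.

    ``outputs`` has shape (D+1, n_out) (or (D+1,) for one output); any
    non-finite value voids the trajectory (ValueError), mirroring the
    successful-trajectory accounting.
    """
    y = np.atleast_2d(np.asarray(outputs, dtype=float).T).T
    if y.shape[0] != traj.points.shape[0]:
        raise ValueError("outputs do not match trajectory length")
    if not np.all(np.isfinite(y)):
        raise ValueError("failed evaluation voids the trajectory")
    n_dim = traj.points.shape[1]
    ee = np.empty((n_dim, y.shape[1]))
    for k, i in enumerate(traj.order):
        ee[i] = (y[k + 1] - y[k]) / traj.signed_delta[k]
    return ee


def mu_star(ee_stack: np.ndarray) -> np.ndarray:
    """mu* = mean |EE| over trajectories; stack shape (n_traj, D, n_out)."""
    return np.abs(ee_stack).mean(axis=0)


def classify_importance(mu: np.ndarray,
                        ci_upper: Optional[np.ndarray] = None) -> np.ndarray:
    """Keep mask: mu* (or its CI upper bound) at or above the
    across-parameter mean for at least one output."""
    mu = np.atleast_2d(mu.T).T
    mean = mu.mean(axis=0, keepdims=True)
    stat = mu if ci_upper is None else np.atleast_2d(ci_upper.T).T
    with np.errstate(invalid="ignore"):
        keep = (stat >= mean) & (mean > 0)
    return keep.any(axis=1)


def converged(ee_stack: np.ndarray) -> bool:
    """Leave-one-out stability of the importance classification."""
    n_traj = ee_stack.shape[0]
    if n_traj < 2:
        return False
    abs_ee = np.abs(ee_stack)
    total = abs_ee.sum(axis=0)
    base = classify_importance(total / n_traj)
    for t in range(n_traj):
        mu_loo = (total - abs_ee[t]) / (n_traj - 1)
        if not np.array_equal(classify_importance(mu_loo), base):
            return False
    return True


def bootstrap_ci(ee_stack: np.ndarray, cfg: MorrisConfig,
                 rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Percentile 95% CI of mu* from trajectory resampling."""
    n_traj = ee_stack.shape[0]
    abs_ee = np.abs(ee_stack)
    stats = np.empty((cfg.n_boot,) + ee_stack.shape[1:])
    for b in range(cfg.n_boot):
        idx = rng.integers(0, n_traj, size=n_traj)
        stats[b] = abs_ee[idx].mean(axis=0)
    return (np.percentile(stats, 2.5, axis=0),
            np.percentile(stats, 97.5, axis=0))


def screen(evaluate: Callable[[np.ndarray], Optional[np.ndarray]],
           n_dim: int, cfg: MorrisConfig,
           rng: Optional[np.random.Generator] = None,
           log: Optional[dict] = None) -> MorrisResult:
    """One screening pass: sample trajectories until the leave-one-out
    classification is stable (or the budget is exhausted, then decide by
    bootstrap CI).

    ``evaluate`` maps a normalized point in [0,1]^D to an output vector,
    or returns None / non-finite values on model failure.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    effects: List[np.ndarray] = []
    attempted = 0
    target = cfg.min_traj
    use_ci = False
    attempt_cap = 200 * max(cfg.max_traj, 1)
    exhausted = False
    while True:
        while len(effects) < target:
            if attempted >= attempt_cap:
                if not effects:
                    raise RuntimeError("no successful trajectories")
                exhausted = True
                break
            attempted += 1
            traj = build_trajectory(n_dim, cfg, rng)
            ys = []
            failed = False
            for point in traj.points:
                y = evaluate(point)
                if y is None or not np.all(np.isfinite(y)):
                    failed = True
                    break
                ys.append(np.atleast_1d(np.asarray(y, dtype=float)))
            if failed:
                continue
            effects.append(elementary_effects(traj, np.vstack(ys)))
        stack = np.stack(effects)
        if exhausted:
            use_ci = True
            break
        if converged(stack):
            break
        if len(effects) >= cfg.max_traj:
            use_ci = True
            break
        target = min(len(effects) + cfg.batch, cfg.max_traj)
    mu = mu_star(stack)
    ci_lo = ci_up = None
    if use_ci:
        ci_lo, ci_up = bootstrap_ci(stack, cfg, rng)
    important = classify_importance(mu, ci_up)
    if log is not None:
        log["n_traj"] = len(effects)
        log["n_attempted"] = attempted
        log["success_rate"] = len(effects) / attempted
        log["converged"] = not use_ci
    return MorrisResult(mu_star=mu, n_traj=len(effects), ci_lower=ci_lo,
                        ci_upper=ci_up, important=important)


@dataclass
class ScreeningLog:
    iterations: List[dict] = field(default_factory=list)


def msm_iterate(evaluate: Callable[[np.ndarray], Optional[np.ndarray]],
                n_dim: int, cfg: MorrisConfig,
                rng: Optional[np.random.Generator] = None,
                reference: Optional[np.ndarray] = None
                ) -> Tuple[np.ndarray, ScreeningLog]:
    """Iterated screening: repeatedly remove parameters that are
    below-average for every output until a fixed point is reached.

    Removed parameters are fixed at their reference position
    (``reference``, default 0.5) in subsequent iterations.  Returns the
    keep mask over the original D parameters and a per-iteration log of
    trajectory counts and success rates.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    reference = np.full(n_dim, 0.5) if reference is None else \
        np.asarray(reference, dtype=float)
    active = np.ones(n_dim, dtype=bool)
    log = ScreeningLog()
    while True:
        idx = np.flatnonzero(active)

        def eval_active(x_active: np.ndarray) -> Optional[np.ndarray]:
            x = reference.copy()
            x[idx] = x_active
            return evaluate(x)

        entry: dict = {"n_active": int(active.sum())}
        result = screen(eval_active, idx.size, cfg, rng, log=entry)
        log.iterations.append(entry)
        keep = result.important
        if keep.all():
            break
        active[idx[~keep]] = False
        if active.sum() == 0:
            break
    return active, log
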