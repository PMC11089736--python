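"""Bundled segmental left-ventricle forward model.

Maps a parameter set to per-segment fiber strain and wall stress traces
plus an LV cavity volume trace over one cardiac cycle.  The model is a
deliberately lightweight phenomenological stand-in for a full closed-loop
cardiovascular model, built behind a narrow contract (parameters in,
:class:`SimulationResult` out) so that a detailed lumped-parameter
binding can be dropped in.

Model structure
---------------
* The LV cavity volume waveform is prescribed by a two-phase template:
  isovolumic contraction, raised-cosine ejection of the stroke volume
  ``SV = q0 * tCycle``, isovolumic relaxation, raised-cosine filling.
  End-diastolic volume follows from the summed reference midwall area.
* Segmental heterogeneity is resolved by a common-tension patch
  constraint: at every instant a single wall tension ``T(t)`` is found
  such that the AmRef-weighted sum of segment midwall areas matches the
  area prescribed by the volume template.  Each segment's sarcomere
  length follows by inverting its tension-length law.
* The per-segment law combines an exponential passive stress
  ``SfPas * (exp(k1*(L/Ls0Pas - 1)) - 1)`` with an active stress
  ``act_i(t) * SfAct * (L - 1)`` gated by a smooth raised-cosine
  activation pulse.  The pulse starts at the segment's mechanical
  activation delay ``dT``; its rise rate scales with ``vMax``/``TR``,
  its duration with the global LV activation duration ``ADO_LV`` and
  the decay delay ``LDAD``, and its decay rate with ``LDCI``/``TD``.

Strain sign convention: shortening is negative, as in longitudinal
strain imaging.  The zero-strain reference is mitral valve closure
(``t = 0`` of the cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .registry import LV_TISSUE_TYPES, ParameterSubset

#: Fixed integration time step (ms).
DT_MS = 2.0
#: Geometric reference sarcomere length (um): segment midwall area is
#: proportional to AmRef * L / L_GEO.
L_GEO = 2.0
#: Mean sarcomere stretch at end diastole relative to L_GEO.
ED_STRETCH = 1.10
#: Cavity fraction of the midwall sphere volume.
CAVITY_FRACTION = 0.85

_SEGMENTAL = set(LV_TISSUE_TYPES) | {"dT"}

_REQUIRED_GLOBALS = ("q0", "tCycle", "dTauAv", "ADO_LV")
_REQUIRED_SEGMENTAL = ("AmRef", "Ls0Pas", "SfPas", "k1", "SfAct", "vMax",
                       "TR", "TD", "LDAD", "LDCI", "dT", "VWall")


class ModelParameterError(ValueError):
    """Raised for malformed or incomplete parameter sets."""


@dataclass
class ModelParameters:
    """Parameter values for one simulation.

    ``scalars`` holds global parameters (including global-offset
    multipliers, suffix ``_GO``); ``segmental`` holds per-segment arrays
    of length ``n_seg`` for LV tissue types and the activation delay
    ``dT``.
    """

    n_seg: int
    scalars: Dict[str, float] = field(default_factory=dict)
    segmental: Dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            n_seg=self.n_seg,
            scalars=dict(self.scalars),
            segmental={k: v.copy() for k, v in self.segmental.items()},
        )

    def set(self, name: str, value: float, segment: Optional[int] = None) -> None:
        if segment is None:
            if name in _SEGMENTAL:
                self.segmental[name] = np.full(self.n_seg, float(value))
            else:
                self.scalars[name] = float(value)
        else:
            self.segmental[name][segment] = float(value)

    def get(self, name: str, segment: Optional[int] = None) -> float:
        if segment is None:
            return self.scalars[name]
        return float(self.segmental[name][segment])

    def effective(self, name: str) -> np.ndarray:
        """Segmental values with the global-offset applied.

        Tissue offsets are multiplicative (neutral at 1); the
        activation-delay offset is additive in ms (neutral at 0).
        """
        base = np.asarray(self.segmental[name], dtype=float)
        if name == "dT":
            return base + float(self.scalars.get("dT_GO", 0.0))
        return base * float(self.scalars.get(name + "_GO", 1.0))

    @property
    def t_cycle(self) -> float:
        return self.scalars["tCycle"]


def reference_parameters(registry: ParameterSubset) -> ModelParameters:
    """Full parameter set at registry reference values.

    ``dT`` defaults to zero for every segment (simultaneous activation).
    """
    n_seg = registry.n_seg
    params = ModelParameters(n_seg=n_seg)
    for s in registry.specs:
        if s.scope == "regional":
            if s.name not in params.segmental:
                params.segmental[s.name] = np.zeros(n_seg)
            params.segmental[s.name][s.segment_index] = s.reference_value
        else:
            params.scalars[s.name] = s.reference_value
    if "dT" not in params.segmental:
        params.segmental["dT"] = np.zeros(n_seg)
    for name, val in registry.fixed.items():
        params.scalars.setdefault(name, val)
    return params


@dataclass
class SimulationResult:
    """Time-gridded per-segment strain/stress plus LV volume and events."""

    time: np.ndarray          # ms, uniform step <= 2 ms
    strain: np.ndarray        # (n_seg, nt), fiber strain in %
    stress: np.ndarray        # (n_seg, nt), wall stress in kPa
    volume: np.ndarray        # (nt,), LV cavity volume in mL
    sarcomere_length: np.ndarray  # (n_seg, nt), um
    events: Dict[str, float]  # {"t0", "AVO", "AVC"} in ms
    success: bool

    @property
    def n_seg(self) -> int:
        return self.strain.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd
        cols = {"time_ms": self.time}
        for i in range(self.n_seg):
            cols[f"seg_{i + 1:02d}"] = self.strain[i]
        cols["volume_mL"] = self.volume
        pd.DataFrame(cols).to_csv(path, index=False)

    def events_to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({**self.events, "success": bool(self.success)}, fh, indent=2)


# ---------------------------------------------------------------------------
# Activation pulse
# ---------------------------------------------------------------------------

def _activation_pulse(t: np.ndarray, onset: np.ndarray, rise: np.ndarray,
                      t_off: np.ndarray, decay: np.ndarray) -> np.ndarray:
    """Smooth raised-cosine activation, shape (n_seg, nt), in [0, 1]."""
    tt = t[None, :] - onset[:, None]
    rise_ = rise[:, None]
    plateau_end = (t_off - onset)[:, None]
    decay_ = decay[:, None]
    act = np.zeros_like(tt)
    # rising half-cosine
    m = (tt >= 0) & (tt < rise_)
    act[m] = 0.5 * (1.0 - np.cos(np.pi * (tt / np.where(rise_ > 0, rise_, 1.0))))[m]
    # plateau
    act[(tt >= rise_) & (tt < plateau_end)] = 1.0
    # decaying half-cosine
    m = (tt >= plateau_end) & (tt < plateau_end + decay_)
    act[m] = 0.5 * (1.0 + np.cos(np.pi * ((tt - plateau_end)
                                          / np.where(decay_ > 0, decay_, 1.0))))[m]
    return act


def _activation(t: np.ndarray, t_cycle: float, dT: np.ndarray, ado: float,
                vmax: np.ndarray, tr: np.ndarray, td: np.ndarray,
                ldad: np.ndarray, ldci: np.ndarray) -> np.ndarray:
    """Periodic activation: pulses of adjacent beats overlap-resolved by max."""
    onset = np.ascontiguousarray(dT, dtype=float)
    rise = 2800.0 * tr / np.maximum(vmax, 1e-6)
    t_off = onset + 0.6 * ado + 30.0 * ldad
    t_off = np.maximum(t_off, onset + rise)
    decay = 480.0 * td / np.maximum(ldci, 1e-6)
    act = np.zeros((onset.size, t.size))
    if _HAVE_NUMBA:
        return _activation_kernel(np.ascontiguousarray(t, dtype=float),
                                  float(t_cycle), onset,
                                  np.ascontiguousarray(rise, dtype=float),
                                  np.ascontiguousarray(t_off, dtype=float),
                                  np.ascontiguousarray(decay, dtype=float), act)
    for shift in (-t_cycle, 0.0, t_cycle):
        act = np.maximum(act, _activation_pulse(t - shift, onset, rise, t_off, decay))
    return act


# ---------------------------------------------------------------------------
# Common-tension wall equilibrium
# ---------------------------------------------------------------------------

_L_FLOOR = 0.2


def _invert_tension_law(T, P, K, L0, A, m0=None, iters=30):
    """Sarcomere length solving ``sigma(L) = T`` per segment and instant.

    Substituting ``m = K*(L/L0 - 1)`` turns the strictly monotone law
    ``sigma = P*(exp(m) - 1) + A*(L - 1)`` into ``P*e^m + B*m = R`` with
    ``B = A*L0/K >= 0`` and ``R = T + P + A - A*L0``.  The left side is
    convex and strictly increasing in ``m``, so Newton iteration
    converges globally (one possible overshoot, then monotone).

    Returns ``(L, E)`` with ``E = exp(m)``; ``m0`` warm-starts the
    iteration.  ``L`` is floored at a small physical length; the floor
    is only reached for tensions far below the physiological range.
    """
    B = A * (L0 / K)
    R = (T + P) + A * (1.0 - L0)
    # analytic start: exact for the passive-only case (B = 0) and an
    # overestimate whenever R > P, giving monotone Newton descent
    m = np.clip(np.log(np.maximum(R, 1e-300) / P), -700.0, 690.0)
    atol = 1e-15 * (np.max(np.abs(R)) + 1.0)
    E = np.empty_like(m)
    f = np.empty_like(m)
    for _ in range(iters):
        np.exp(m, out=E)
        np.multiply(P, E, out=f)
        f += B * m
        f -= R
        if np.max(np.abs(f)) < atol:
            break
        f /= P * E + B
        m -= f
        np.clip(m, -700.0, 690.0, out=m)
    np.exp(m, out=E)
    L = np.maximum(L0 * (1.0 + m / K), _L_FLOOR)
    return L, E, m


def _solve_equilibrium_numpy(
    area_template: np.ndarray,
    am_ref: np.ndarray,
    active_stress: np.ndarray,
    sf_pas: np.ndarray,
    k1: np.ndarray,
    ls0_pas: np.ndarray,
    max_outer: int = 90,
    tol: float = 1e-12,
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Vectorized reference implementation of the equilibrium solve."""
    am_ref = np.asarray(am_ref, dtype=float)
    w = (am_ref / am_ref.sum())[:, None]
    target = L_GEO * np.asarray(area_template, dtype=float)  # mean L, (nt,)
    P = np.asarray(sf_pas, dtype=float)[:, None]
    K = np.asarray(k1, dtype=float)[:, None]
    L0 = np.asarray(ls0_pas, dtype=float)[:, None]
    A = np.asarray(active_stress, dtype=float)
    nt = target.size

    # T = exp(u) - C; C just below the reachable tension minimum
    C = float(P.max()) + 1.0
    u_lo = np.full(nt, -30.0)
    u_hi = np.full(nt, 30.0)

    # initial tension from the homogeneous-length guess
    Lh = np.broadcast_to(target[None, :], A.shape)
    Eh = np.exp(np.clip(K * (Lh / L0 - 1.0), -200.0, 200.0))
    T = (w * (P * (Eh - 1.0) + A * (Lh - 1.0))).sum(axis=0)
    u = np.clip(np.log(np.maximum(T + C, 1e-12)), u_lo + 1e-9, u_hi - 1e-9)

    resid = np.inf
    L = Lh
    prev_gap = np.full(nt, np.inf)
    for _ in range(max_outer):
        T = np.exp(u) - C
        L, E, m = _invert_tension_law(T[None, :], P, K, L0, A)
        gap = (w * L).sum(axis=0) - target
        resid = np.max(np.abs(gap) / target)
        if resid < tol:
            break
        u_lo = np.where(gap < 0.0, u, u_lo)
        u_hi = np.where(gap > 0.0, u, u_hi)
        dsigma = np.maximum(P * K / L0 * E + A, 1e-12)
        dg_du = (w / dsigma).sum(axis=0) * (T + C)
        u_newton = u - gap / np.maximum(dg_du, 1e-300)
        u_mid = 0.5 * (u_lo + u_hi)
        # take the Newton step only while it stays in the bracket and
        # keeps halving the constraint gap; otherwise bisect, which
        # guarantees convergence on the monotone tension residual
        ok_step = (u_newton > u_lo) & (u_newton < u_hi) \
            & (np.abs(gap) <= 0.5 * prev_gap)
        settled = np.abs(gap) / target < tol
        u = np.where(settled, u, np.where(ok_step, u_newton, u_mid))
        prev_gap = np.abs(gap)
    T = np.exp(u) - C
    L, E, m = _invert_tension_law(T[None, :], P, K, L0, A)
    gap = (w * L).sum(axis=0) - target
    resid = np.max(np.abs(gap) / target)
    converged = bool(resid < 1e-8) and bool(np.all(np.isfinite(L))) \
        and bool(np.all(np.isfinite(T)))
    return L, T, converged


try:  # compiled per-time-column kernel; falls back to the vectorized path
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:
    @_njit(cache=True)
    def _equilibrium_kernel(target, w, P, K, L0, A, L_out, T_out):  # pragma: no cover
        n_seg, nt = A.shape
        Pmax = P[0]
        for i in range(1, n_seg):
            if P[i] > Pmax:
                Pmax = P[i]
        C = Pmax + 1.0
        max_resid = 0.0
        u_prev = np.nan
        m_cur = np.empty(n_seg)
        have_m = False
        for j in range(nt):
            tgt = target[j]
            # homogeneous-length initial tension
            T = 0.0
            for i in range(n_seg):
                m = K[i] * (tgt / L0[i] - 1.0)
                if m > 200.0:
                    m = 200.0
                T += w[i] * (P[i] * (np.exp(m) - 1.0) + A[i, j] * (tgt - 1.0))
            u_lo, u_hi = -30.0, 30.0
            tc = T + C
            if tc < 1e-12:
                tc = 1e-12
            # warm start from the previous instant (tension is smooth
            # in time); first column uses the homogeneous guess
            u = u_prev if u_prev == u_prev else np.log(tc)
            if u <= u_lo:
                u = u_lo + 1e-9
            if u >= u_hi:
                u = u_hi - 1e-9
            prev_gap = 1e300
            resid = 1e300
            for _ in range(90):
                T = np.exp(u) - C
                g = -tgt
                dgdT = 0.0
                for i in range(n_seg):
                    B = A[i, j] * (L0[i] / K[i])
                    R = (T + P[i]) + A[i, j] * (1.0 - L0[i])
                    Rp = R if R > 1e-300 else 1e-300
                    atol = 1e-15 * (abs(R) + 1.0)
                    # warm start (convex monotone law: Newton converges
                    # from any start); analytic restart if it stalls
                    for attempt in range(2):
                        if attempt == 0 and have_m:
                            m = m_cur[i]
                        else:
                            m = np.log(Rp / P[i])
                        if m > 690.0:
                            m = 690.0
                        elif m < -700.0:
                            m = -700.0
                        f = 1e300
                        for _k in range(60):
                            E = np.exp(m)
                            f = P[i] * E + B * m - R
                            if abs(f) < atol:
                                break
                            m -= f / (P[i] * E + B)
                            if m > 690.0:
                                m = 690.0
                            elif m < -700.0:
                                m = -700.0
                        if abs(f) < atol or m <= -700.0 or not have_m:
                            break
                    E = np.exp(m)
                    m_cur[i] = m
                    L = L0[i] * (1.0 + m / K[i])
                    if L < _L_FLOOR:
                        L = _L_FLOOR
                    L_out[i, j] = L
                    ds = P[i] * K[i] / L0[i] * E + A[i, j]
                    if ds < 1e-12:
                        ds = 1e-12
                    g += w[i] * L
                    dgdT += w[i] / ds
                agap = abs(g)
                resid = agap / tgt
                if resid < 1e-12:
                    break
                if g < 0.0:
                    u_lo = u
                else:
                    u_hi = u
                dgdu = dgdT * (T + C)
                if dgdu < 1e-300:
                    dgdu = 1e-300
                un = u - g / dgdu
                # accept the Newton step while it stays bracketed and the
                # gap keeps shrinking (or is already tiny); bisect otherwise
                if un > u_lo and un < u_hi and (agap <= 0.5 * prev_gap
                                                or resid < 1e-9):
                    u = un
                else:
                    u = 0.5 * (u_lo + u_hi)
                prev_gap = agap
            T_out[j] = np.exp(u) - C
            u_prev = u
            have_m = True
            if resid > max_resid:
                max_resid = resid
        return max_resid

    @_njit(cache=True)
    def _activation_kernel(t, t_cycle, onset, rise, t_off, decay, act):  # pragma: no cover
        n_seg = onset.size
        nt = t.size
        for i in range(n_seg):
            r = rise[i] if rise[i] > 0.0 else 1.0
            d = decay[i] if decay[i] > 0.0 else 1.0
            plateau = t_off[i] - onset[i]
            for j in range(nt):
                best = 0.0
                for shift in (-t_cycle, 0.0, t_cycle):
                    tt = t[j] - shift - onset[i]
                    if tt < 0.0 or tt >= plateau + d:
                        continue
                    if tt < r:
                        val = 0.5 * (1.0 - np.cos(np.pi * tt / r))
                    elif tt < plateau:
                        val = 1.0
                    else:
                        val = 0.5 * (1.0 + np.cos(np.pi * (tt - plateau) / d))
                    if val > best:
                        best = val
                act[i, j] = best
        return act


def solve_wall_equilibrium(
    area_template: np.ndarray,
    am_ref: np.ndarray,
    active_stress: np.ndarray,
    sf_pas: np.ndarray,
    k1: np.ndarray,
    ls0_pas: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, bool]:
    """Solve the patch constraint for sarcomere lengths and common tension.

    Finds ``T(t)`` such that ``sum_i AmRef_i * L_i(T) / L_GEO`` equals
    ``sum_i AmRef_i * area_template(t)``, where each ``L_i`` inverts the
    segment's strictly monotone tension-length law

        ``T = SfPas_i * (exp(k1_i * (L/Ls0Pas_i - 1)) - 1)
             + active_stress_i(t) * (L - 1)``.

    The aggregate constraint is solved per time point by a safeguarded
    Newton iteration in ``u = log(T + C)`` (the passive branch is nearly
    linear in ``u``), with a guaranteed bisection bracket as fallback.
    A compiled per-time-column kernel is used when available; the
    vectorized implementation is equivalent and serves as reference.

    Returns ``(L, T, converged)`` with ``L`` of shape (n_seg, nt).
    Only the relative AmRef weights enter, so a uniform rescaling of all
    AmRef with a fixed area template leaves the strains unchanged.
    """
    if not _HAVE_NUMBA:  # pragma: no cover
        return _solve_equilibrium_numpy(area_template, am_ref, active_stress,
                                        sf_pas, k1, ls0_pas)
    am_ref = np.ascontiguousarray(am_ref, dtype=float)
    w = am_ref / am_ref.sum()
    target = L_GEO * np.ascontiguousarray(area_template, dtype=float)
    A = np.ascontiguousarray(active_stress, dtype=float)
    L = np.empty_like(A)
    T = np.empty_like(target)
    max_resid = _equilibrium_kernel(
        target, w, np.ascontiguousarray(sf_pas, dtype=float),
        np.ascontiguousarray(k1, dtype=float),
        np.ascontiguousarray(ls0_pas, dtype=float), A, L, T)
    converged = bool(max_resid < 1e-8) and bool(np.all(np.isfinite(L))) \
        and bool(np.all(np.isfinite(T)))
    return L, T, converged


# ---------------------------------------------------------------------------
# Volume template and simulation
# ---------------------------------------------------------------------------

def _volume_template(t: np.ndarray, t_cycle: float, sv: float, edv: float,
                     d_tau_av: float) -> Tuple[np.ndarray, Dict[str, float], bool]:
    t_avo = 0.05 * t_cycle + d_tau_av
    t_ej = 0.30 * t_cycle
    t_avc = t_avo + t_ej
    t_mvo = t_avc + 0.12 * t_cycle
    ok = (0.0 <= t_avo < t_avc < t_mvo < t_cycle) and sv > 0 and edv - sv > 5.0
    esv = edv - sv
    v = np.full_like(t, edv)
    if ok:
        m = (t >= t_avo) & (t < t_avc)
        u = (t[m] - t_avo) / t_ej
        v[m] = edv - sv * 0.5 * (1.0 - np.cos(np.pi * u))
        v[(t >= t_avc) & (t < t_mvo)] = esv
        m = t >= t_mvo
        uu = (t[m] - t_mvo) / (t_cycle - t_mvo)
        v[m] = esv + sv * 0.5 * (1.0 - np.cos(np.pi * uu))
    events = {"t0": 0.0, "AVO": t_avo, "AVC": t_avc}
    return v, events, ok


def end_diastolic_volume(am_ref_total: float) -> float:
    """Cavity volume (mL) of the midwall sphere spanned by the summed
    reference area (cm^2)."""
    r = np.sqrt(am_ref_total / (4.0 * np.pi))
    return CAVITY_FRACTION * (4.0 / 3.0) * np.pi * r ** 3


def simulate(params: ModelParameters, n_seg: Optional[int] = None) -> SimulationResult:
    """Run one cardiac cycle.  Deterministic for fixed parameters.

    Non-physiological parameter sets return ``success=False`` rather than
    raising; malformed parameter sets raise :class:`ModelParameterError`.
    """
    if n_seg is None:
        n_seg = params.n_seg
    if n_seg != params.n_seg:
        raise ModelParameterError(
            f"parameter set is for {params.n_seg} segments, requested {n_seg}")
    for name in _REQUIRED_GLOBALS:
        if name not in params.scalars:
            raise ModelParameterError(f"missing global parameter {name!r}")
    for name in _REQUIRED_SEGMENTAL:
        if name not in params.segmental:
            raise ModelParameterError(f"missing segmental parameter {name!r}")
        if len(params.segmental[name]) != n_seg:
            raise ModelParameterError(f"segmental parameter {name!r} has wrong length")

    tc = float(params.scalars["tCycle"])
    if not np.isfinite(tc) or tc <= 0:
        raise ModelParameterError("tCycle must be positive")
    nt = int(np.ceil(tc / DT_MS)) + 1
    t = np.linspace(0.0, tc, nt)

    am_ref = params.effective("AmRef")
    sv = float(params.scalars["q0"]) * tc / 1000.0
    edv = end_diastolic_volume(float(am_ref.sum()))
    volume, events, ok_template = _volume_template(
        t, tc, sv, edv, float(params.scalars["dTauAv"]))

    area = ED_STRETCH * ((volume + edv) / (2.0 * edv)) ** (2.0 / 3.0)

    act = _activation(
        t, tc, params.effective("dT"),
        float(params.scalars["ADO_LV"]) * float(params.scalars.get("ADO_LV_GO", 1.0)),
        params.effective("vMax"), params.effective("TR"), params.effective("TD"),
        params.effective("LDAD"), params.effective("LDCI"),
    )
    active_stress = params.effective("SfAct")[:, None] * act

    L, T, converged = solve_wall_equilibrium(
        area, am_ref, active_stress,
        params.effective("SfPas"), params.effective("k1"),
        params.effective("Ls0Pas"),
    )
    strain = (L - L[:, :1]) / L[:, :1] * 100.0
    stress = np.broadcast_to(T, (n_seg, t.size)).copy()
    success = bool(ok_template and converged and np.all(volume > 0))
    return SimulationResult(
        time=t, strain=strain, stress=stress, volume=volume,
        sarcomere_length=L, events=events, success=success,
    )


# ---------------------------------------------------------------------------
# Strain post-processing
# ---------------------------------------------------------------------------

def fiber_strain(time: np.ndarray, ls_trace: np.ndarray, t0: float) -> np.ndarray:
    """Fiber strain (%) of a sarcomere-length trace referenced to ``t0``.

    ``eps(t) = (L(t) - L(t0)) / L(t0) * 100`` with ``t0`` the timing of
    mitral valve closure; ``eps(t0) = 0`` by construction.
    """
    time = np.asarray(time, dtype=float)
    ls = np.asarray(ls_trace, dtype=float)
    if np.any(ls <= 0):
        raise ValueError("sarcomere length must be positive")
    if not (time[0] <= t0 <= time[-1]):
        raise ValueError("t0 outside the trace")
    l0 = np.interp(t0, time, ls)
    return (ls - l0) / l0 * 100.0


def scale_strain_to_measurement(sim_strain: np.ndarray,
                                measured_global_peak: float) -> np.ndarray:
    """Scale simulated fiber strain to the measured strain amplitude.

    Every segmental trace is multiplied by the ratio of the measured to
    the simulated peak of the global signal, the global signal being the
    average strain of all segments and its peak the most negative value.
    """
    sim_strain = np.asarray(sim_strain, dtype=float)
    glob = sim_strain.mean(axis=0)
    peak = glob[np.argmin(glob)]
    if peak == 0.0:
        raise ValueError("simulated global strain peak is zero; cannot scale")
    return sim_strain * (measured_global_peak / peak)
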