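"""Numerical integration of the HKB equations and slow-flow analysis.

Provides deterministic adaptive integration of

* the full and linear oscillator models (4-D state, fast time t),
* the dimensional averaged slow flow (r1, r2, phi; fast time t),
* the two nondimensional slow flows (R1, R2, phi; slow times s, s~),

plus analytic-signal extraction of per-oscillator amplitude and phase
from full-model trajectories, and steady-state settling detection that
matches the settled slow-flow state against the closed-form catalogue.

There is no randomness anywhere: results are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import hilbert

from . import steady_states
from .model_core import HKBParams, full_hkb_rhs, linear_hkb_rhs
from .nondim import (
    GUARD_RADIUS,
    AltNondimParams,
    NondimParams,
    PolarState,
    ahkb_rhs_alt,
    ahkb_rhs_dimensional,
    ahkb_rhs_nondim,
    wrap_phase,
)

__all__ = [
    "BLOWUP_NORM",
    "Trajectory",
    "SlowFlowSeries",
    "SettleResult",
    "integrate",
    "extract_slow_flow",
    "settle",
]

#: State norm beyond which a trajectory is declared divergent (relevant in
#: the negative-damping regime where energy grows without bound).
BLOWUP_NORM = 1e6

#: rhs_id -> (callable(y, params), polar?, time convention)
_RHS = {
    "full": (lambda y, p: full_hkb_rhs(y, p), False, "t"),
    "linear": (lambda y, p: linear_hkb_rhs(y, p), False, "t"),
    "ahkb_dim": (lambda y, p: np.asarray(
        ahkb_rhs_dimensional(y[0], y[1], y[2], p)), True, "t"),
    "ahkb": (lambda y, p: np.asarray(
        ahkb_rhs_nondim(y, p, _guarded=False)), True, "s"),
    "ahkb_alt": (lambda y, p: np.asarray(
        ahkb_rhs_alt(y, p, _guarded=False)), True, "s_tilde"),
}


@dataclass(frozen=True)
class Trajectory:
    """Time series of a model state.

    ``states`` has one row per time, columns (x1, x2, v1, v2) for the
    oscillator models or (R1, R2, phi) for the polar slow flows (phi is
    stored unwrapped for continuity; wrap on use).  ``time_convention``
    is ``t`` (physical), ``s`` (slow time gamma t / 2) or ``s_tilde``
    (slow time |a| t / 2).
    """

    times: np.ndarray
    states: np.ndarray
    time_convention: str
    rhs_id: str
    diverged: bool = False
    guarded: bool = False

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times/states length mismatch")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class SlowFlowSeries:
    """Per-cycle amplitude/phase estimates extracted from a fast trajectory."""

    times: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    phi: np.ndarray          # relative phase phi1 - phi2, wrapped
    phi1: np.ndarray | None = None
    phi2: np.ndarray | None = None


@dataclass(frozen=True)
class SettleResult:
    """Outcome of steady-state settling detection."""

    converged: bool
    final_state: PolarState
    matched_branch: str
    residual: float


def integrate(rhs_id: str, params, init, t_end: float,
              rtol: float = 1e-9, atol: float = 1e-11,
              t_eval=None, method: str = "RK45") -> Trajectory:
    """Integrate one of the registered models with an adaptive RK scheme.

    ``rhs_id`` is one of ``full``, ``linear`` (params: HKBParams, 4-D
    state), ``ahkb_dim`` (HKBParams, polar state), ``ahkb``
    (NondimParams) or ``ahkb_alt`` (AltNondimParams).  Integration stops
    early with ``diverged=True`` when the state norm exceeds 1e6, and,
    for the polar flows, with ``guarded=True`` when either amplitude
    falls below the guard radius (the relative phase becomes singular
    there; the trajectory is collapsing onto the Z family).
    """
    if rhs_id not in _RHS:
        raise KeyError(f"unknown rhs_id {rhs_id!r}; choose from {sorted(_RHS)}")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    fn, polar, convention = _RHS[rhs_id]
    y0 = np.asarray(init.as_array() if hasattr(init, "as_array") else init,
                    dtype=float)

    def rhs(t, y):
        return fn(y, params)

    def blowup(t, y):
        return float(np.linalg.norm(y) - BLOWUP_NORM)
    blowup.terminal = True

    events = [blowup]
    if polar:
        def guard(t, y):
            return float(min(y[0], y[1]) - GUARD_RADIUS)
        guard.terminal = True
        events.append(guard)

    sol = solve_ivp(rhs, (0.0, t_end), y0, method=method, rtol=rtol, atol=atol,
                    t_eval=t_eval, events=events, dense_output=False)
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"integration failed: {sol.message}")
    diverged = sol.status == 1 and len(sol.t_events[0]) > 0
    guarded = polar and sol.status == 1 and len(sol.t_events[1]) > 0
    times, states = sol.t, sol.y.T
    if times[0] > 0.0:  # t_eval may skip t=0; keep invariant simple
        times = np.concatenate([[0.0], times])
        states = np.vstack([y0, states])
    return Trajectory(times, states, convention, rhs_id,
                      diverged=diverged, guarded=guarded)


def extract_slow_flow(traj: Trajectory, omega: float | None = None,
                      method: str = "quadrature",
                      trim_fraction: float = 0.05) -> SlowFlowSeries:
    """Estimate slowly varying amplitudes and relative phase of a
    full/linear-model trajectory.

    The default route builds the analytic signal from the state itself,
    z_i = x_i - i v_i / omega, which is exact for a narrowband carrier
    x_i = r_i cos(omega t + phi_i) (the averaging ansatz); it gives
    r_i = |z_i| and phi = arg(z1 conj(z2)) sample by sample with no edge
    effects.  ``method="hilbert"`` forms z_i = x_i + i H[x_i] on a
    uniform resampling instead (positions only; edges trimmed by
    ``trim_fraction`` per side to suppress spectral leakage), and
    ``method="peaks"`` falls back to one amplitude/phase estimate per
    oscillation period from peak detection.
    """
    if traj.states.shape[1] != 4:
        raise ValueError("slow-flow extraction needs a 4-D oscillator trajectory")
    w = omega if omega is not None else _dominant_omega(traj)
    span = traj.times[-1] - traj.times[0]
    period = 2.0 * math.pi / w
    if span < 10.0 * period:
        raise ValueError(
            f"trajectory spans {span/period:.1f} periods; need >= 10 for "
            "slow-flow extraction")
    if method == "peaks":
        return _extract_peaks(traj, w)
    if method == "quadrature":
        t = traj.times
        z1 = traj.states[:, 0] - 1j * traj.states[:, 2] / w
        z2 = traj.states[:, 1] - 1j * traj.states[:, 3] / w
        sl = slice(None)
    elif method == "hilbert":
        n = max(4096, 64 * int(span / period))
        t = np.linspace(traj.times[0], traj.times[-1], n)
        z1 = hilbert(np.interp(t, traj.times, traj.states[:, 0]))
        z2 = hilbert(np.interp(t, traj.times, traj.states[:, 1]))
        cut = max(int(n * trim_fraction), int(n * period / span) + 1)
        sl = slice(cut, n - cut)
    else:
        raise ValueError("method must be 'quadrature', 'hilbert' or 'peaks'")
    phi = np.angle(z1[sl] * np.conj(z2[sl]))
    phi1 = np.array([wrap_phase(v) for v in
                     np.unwrap(np.angle(z1[sl])) - w * t[sl]])
    phi2 = np.array([wrap_phase(v) for v in
                     np.unwrap(np.angle(z2[sl])) - w * t[sl]])
    return SlowFlowSeries(t[sl], np.abs(z1[sl]), np.abs(z2[sl]), phi,
                          phi1, phi2)


def _dominant_omega(traj: Trajectory) -> float:
    """Dominant angular frequency of x1 via the discrete Fourier transform."""
    t = np.linspace(traj.times[0], traj.times[-1], 4096)
    x = np.interp(t, traj.times, traj.states[:, 0])
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(t.size, d=t[1] - t[0])
    return 2.0 * math.pi * freqs[int(np.argmax(spec[1:])) + 1]


def _extract_peaks(traj: Trajectory, w: float) -> SlowFlowSeries:
    from scipy.signal import find_peaks
    period = 2.0 * math.pi / w
    n = max(2048, 64 * int((traj.times[-1] - traj.times[0]) / period))
    t = np.linspace(traj.times[0], traj.times[-1], n)
    dt = t[1] - t[0]
    min_dist = max(1, int(0.8 * period / dt))
    x = [np.interp(t, traj.times, traj.states[:, i]) for i in (0, 1)]
    peaks = [find_peaks(xi, distance=min_dist)[0] for xi in x]
    k = min(len(peaks[0]), len(peaks[1]))
    if k < 3:
        raise ValueError("too few oscillation peaks for extraction")
    p1, p2 = peaks[0][:k], peaks[1][:k]
    times = t[p1]
    r1 = x[0][p1]
    r2 = np.interp(times, t[p2], x[1][p2])
    # cos(w t + phi_i) peaks at w t + phi_i = 2 pi k  =>  phi_i = -w t_peak
    phi1 = np.array([wrap_phase(-w * tv) for tv in t[p1]])
    phi2 = np.array([wrap_phase(-w * tv) for tv in t[p2]])
    phi = np.array([wrap_phase(a - b) for a, b in
                    zip(phi1, np.interp(times, t[p2], np.unwrap(phi2)))])
    return SlowFlowSeries(times, r1, r2, phi, phi1, None)


# ---------------------------------------------------------------------------
# settling detection
# ---------------------------------------------------------------------------

def _match_branch(y: np.ndarray, mu: float, kappa: float,
                  match_tol: float) -> tuple[str, float]:
    """Nearest catalogue branch to a settled polar state."""
    best, best_d = "none", math.inf
    for label in steady_states.ALL_BRANCHES:
        br = steady_states.branch_value(label, mu, kappa,
                                        attach_eigenvalues=False)
        if not br.exists or math.isnan(br.R1_star):
            continue
        dphi = (0.0 if math.isnan(br.phi_star)
                else wrap_phase(y[2] - br.phi_star))
        # near-zero amplitudes make the phase meaningless
        if min(br.R1_star, br.R2_star) < 10 * GUARD_RADIUS and label.startswith("Z"):
            dphi = 0.0
        d = math.hypot(y[0] - br.R1_star, y[1] - br.R2_star)
        d = math.hypot(d, dphi)
        if d < best_d:
            best, best_d = label, d
    return (best, best_d) if best_d <= match_tol else ("none", best_d)


def settle(rhs_id: str, params, init, max_time: float = 500.0,
           window: float = 10.0, var_tol: float = 1e-8,
           match_tol: float = 1e-2) -> SettleResult:
    """Integrate a polar slow flow until it stops moving, then identify the
    attained steady state.

    Convergence requires every state component to vary by less than
    ``var_tol`` over a trailing window of ``window`` slow-time units.
    Integration proceeds in chunks so well-behaved runs stop early.  A
    trajectory entering the amplitude guard is classified as reaching
    the degenerate Z family (by its final phase).  Stable steady states
    of the slow flow correspond to stable limit cycles of the full
    oscillator model.
    """
    if rhs_id not in ("ahkb", "ahkb_alt", "ahkb_dim"):
        raise KeyError("settle expects a polar slow flow: "
                       "'ahkb', 'ahkb_alt' or 'ahkb_dim'")
    chunk = max(5.0 * window, 0.1 * max_time)
    npts = 200
    y = np.asarray(init.as_array() if hasattr(init, "as_array") else init,
                   dtype=float)
    elapsed, converged, guarded = 0.0, False, False
    while elapsed < max_time:
        step = min(chunk, max_time - elapsed)
        traj = integrate(rhs_id, params, y, step,
                         t_eval=np.linspace(0.0, step, npts))
        y = traj.final_state.copy()
        elapsed += traj.times[-1]
        if traj.guarded or traj.diverged:
            guarded = traj.guarded
            break
        tail = traj.states[traj.times >= traj.times[-1] - window]
        comp = tail.copy()
        comp[:, 2] = np.unwrap(comp[:, 2])
        if tail.shape[0] >= 5 and np.all(np.ptp(comp, axis=0) < var_tol):
            converged = True
            break

    final = PolarState(max(y[0], 0.0), max(y[1], 0.0), wrap_phase(y[2]))

    if guarded:
        phi = final.phi
        label = ("Z0" if abs(phi) < math.pi / 4
                 else "Zpi" if abs(abs(phi) - math.pi) < math.pi / 4
                 else "Zphi")
        return SettleResult(True, final, label, 0.0)

    mu_kappa = _as_mu_kappa(rhs_id, params)
    if converged and mu_kappa is not None:
        ys = final.as_array()
        if rhs_id == "ahkb_alt":
            ys = _alt_to_mu_kappa_state(ys, params)
            if ys is None:
                return SettleResult(converged, final, "none", math.inf)
        elif rhs_id == "ahkb_dim":
            from .nondim import scale_factors
            r_scale = scale_factors(params, "signed").r_scale
            ys = np.array([ys[0] / r_scale, ys[1] / r_scale, ys[2]])
        label, dist = _match_branch(ys, *mu_kappa, match_tol)
        return SettleResult(converged, final, label, dist)
    return SettleResult(converged, final, "none", math.inf)


def _as_mu_kappa(rhs_id: str, params) -> tuple[float, float] | None:
    if rhs_id == "ahkb" and isinstance(params, NondimParams):
        if params.s_gamma == 1 and params.s_delta == 1:
            return params.mu, params.kappa
        return None  # catalogue printed for the ++ sign case only
    if rhs_id == "ahkb_alt" and isinstance(params, AltNondimParams):
        if params.nu == 0 or params.sigma == 0:
            return None
        mu, kappa = 1.0 / params.nu, 1.0 / params.sigma
        s_gamma = params.s_a * (1 if params.nu > 0 else -1)
        s_delta = params.s_d * (1 if params.sigma > 0 else -1)
        if s_gamma == 1 and s_delta == 1:
            return mu, kappa
        return None
    if rhs_id == "ahkb_dim" and isinstance(params, HKBParams):
        from .nondim import to_mu_kappa
        try:
            p = to_mu_kappa(params)
        except ZeroDivisionError:
            return None
        return (p.mu, p.kappa) if p.s_gamma == 1 and p.s_delta == 1 else None
    return None


def _alt_to_mu_kappa_state(y: np.ndarray, p: AltNondimParams):
    """Rescale an alternative-convention state onto the (mu, kappa) amplitude
    scale: R = R_alt * sqrt(mu/kappa) (real only when mu/kappa > 0)."""
    mu, kappa = 1.0 / p.nu, 1.0 / p.sigma
    if mu / kappa <= 0:
        return None
    f = math.sqrt(mu / kappa)
    return np.array([y[0] * f, y[1] * f, y[2]])
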