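"""Parameter sweeps, transition detection, analytic-vs-numeric comparison
and named literature fixtures.

A one-parameter sweep along a vertical line sigma = const in the
(sigma, nu) plane traverses a family of dimensional models (for example
gamma varying at fixed couplings); the steady-state catalogue predicts
the branch sets along the line and the five analytic bifurcation lines
predict where they change.  Direct simulation of the full oscillator
model provides the independent check on those predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from . import steady_states
from .model_core import HKBParams, hopf_amplitude_inphase
from .nondim import (
    AltNondimParams,
    NondimParams,
    ahkb_rhs_nondim,
    dimensionalize_steady_state,
    scale_factors,
    to_mu_kappa,
    to_nu_sigma,
)
from .simulate import extract_slow_flow, integrate
from .steady_states import MAIN_BRANCHES, bifurcation_lines, branch_value

__all__ = [
    "SweepResult",
    "sweep_nu_line",
    "detect_transition",
    "compare_analytic_numeric",
    "fixtures",
    "fixture",
]


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a one-parameter sweep.

    ``records`` holds one row per (grid point, branch); ``transitions``
    one dict per detected change of the branch set, with the matching
    analytic line label where one applies (``line=None`` flags an
    unexplained transition, a candidate large-amplitude effect).
    """

    parameter: str
    grid: np.ndarray
    records: pd.DataFrame
    transitions: list = field(default_factory=list)


def detect_transition(scalar_fn, lo: float, hi: float, tol: float = 1e-8) -> float:
    """Locate a sign change of ``scalar_fn`` on [lo, hi] by bisection.

    Raises ``ValueError`` when the endpoint values do not bracket a root.
    """
    if not hi > lo:
        raise ValueError("need hi > lo")
    f_lo, f_hi = scalar_fn(lo), scalar_fn(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(f"no sign change on [{lo}, {hi}]: "
                         f"f(lo)={f_lo:.3g}, f(hi)={f_hi:.3g}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = scalar_fn(mid)
        if f_mid == 0.0:
            return mid
        if f_lo * f_mid < 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# sweep along a sigma = const line
# ---------------------------------------------------------------------------

def _classify_analytic(mu: float, kappa: float):
    existing, stable, rows = [], [], []
    for label in MAIN_BRANCHES:
        br = branch_value(label, mu, kappa)
        if br.exists:
            existing.append(label)
            if br.stable is True:
                stable.append(label)
            rows.append(br)
    return tuple(existing), tuple(stable), rows


_GENERIC_SEEDS = ((1.0, 1.0, 0.0), (1.0, 1.0, math.pi), (0.6, 1.4, 0.0),
                  (1.4, 0.6, math.pi), (1.0, 1.0, math.pi / 2.0),
                  (0.5, 0.5, 0.0), (0.5, 0.5, math.pi))


def _classify_numeric(p: NondimParams):
    """Equilibria of the sign-generalised flow by Newton refinement.

    Seeds come from the catalogue formulas (which solve the ++ sign case)
    plus a handful of generic states; converged distinct roots are
    classified by the finite-difference Jacobian.  Labels are geometric:
    EQ0 / EQpi / EQlag for equal amplitudes, UNEQ* otherwise.
    """
    seeds = list(_GENERIC_SEEDS)
    for label in MAIN_BRANCHES:
        br = branch_value(label, p.mu, p.kappa, attach_eigenvalues=False)
        if not math.isnan(br.R1_star) and min(br.R1_star, br.R2_star) > 1e-3:
            seeds.append((br.R1_star, br.R2_star, br.phi_star))
    roots = []
    for seed in seeds:
        sol = root(lambda y: ahkb_rhs_nondim(y, p, _guarded=False),
                   np.asarray(seed), tol=1e-12)
        if not sol.success:
            continue
        y = sol.x
        if min(y[0], y[1]) < 1e-3:  # collapsed to the degenerate family
            continue
        if any(np.linalg.norm(y - r) < 1e-6 for r in roots):
            continue
        roots.append(y)
    existing, stable, rows = [], [], []
    for y in roots:
        eigs = steady_states.numerical_jacobian_eigs(y, p, residual_tol=1e-8)
        is_stable = max(eigs.real) < -steady_states.LINE_TOL
        phi = abs(math.remainder(y[2], 2.0 * math.pi))
        equal = abs(y[0] - y[1]) < 1e-6
        kind = ("EQ" if equal else "UNEQ") + (
            "0" if phi < 1e-3 else "pi" if abs(phi - math.pi) < 1e-3 else "lag")
        existing.append(kind)
        rows.append((kind, y, is_stable))
        if is_stable:
            stable.append(kind)
    return tuple(sorted(existing)), tuple(sorted(stable)), rows


def sweep_nu_line(sigma_fixed: float, nu_grid, s_a: int = 1, s_d: int = 1,
                  refine: bool = True, tol: float = 1e-10) -> SweepResult:
    """Predict branch sets along a vertical line sigma = const.

    Each grid value of nu maps to (mu, kappa) = (1/nu, 1/sigma) with
    sign flags s_gamma = s_a * sgn(nu), s_delta = s_d * sgn(sigma).
    Where both flags are +1 the closed-form catalogue applies and
    transitions are refined against the analytic bifurcation lines;
    elsewhere equilibria are located and classified numerically.
    """
    if sigma_fixed == 0.0:
        raise ValueError("sigma = 0 is degenerate; use the (mu, kappa) or "
                         "dimensional interface")
    nu_grid = np.asarray(nu_grid, dtype=float)
    if np.any(nu_grid == 0.0):
        raise ValueError("nu = 0 is degenerate (gamma = 0); remove it from "
                         "the grid or sweep in dimensional form")
    kappa = 1.0 / sigma_fixed
    s_sigma = 1 if sigma_fixed > 0 else -1
    rows, keys = [], []
    for nu in nu_grid:
        mu = 1.0 / nu
        s_gamma = s_a * (1 if nu > 0 else -1)
        s_delta = s_d * s_sigma
        analytic = s_gamma == 1 and s_delta == 1
        if analytic:
            existing, stable, brs = _classify_analytic(mu, kappa)
            for br in brs:
                rows.append({"nu": nu, "mu": mu, "kappa": kappa,
                             "branch": br.label, "R1": br.R1_star,
                             "R2": br.R2_star, "phi": br.phi_star,
                             "stable": br.stable is True, "source": "analytic"})
        else:
            # Eq-43-style field: mu, kappa keep their signed definitions;
            # the sign flags carry sgn(gamma), sgn(delta)
            p = NondimParams(mu, kappa, s_gamma, s_delta)
            existing, stable, brs = _classify_numeric(p)
            for kind, y, is_stable in brs:
                rows.append({"nu": nu, "mu": mu, "kappa": kappa,
                             "branch": kind, "R1": y[0], "R2": y[1],
                             "phi": y[2], "stable": is_stable,
                             "source": "numeric"})
            if not brs:  # keep one schema-complete row per grid point
                rows.append({"nu": nu, "mu": mu, "kappa": kappa,
                             "branch": "none", "R1": math.nan,
                             "R2": math.nan, "phi": math.nan,
                             "stable": False, "source": "numeric"})
        keys.append((analytic, existing, stable))

    transitions = []
    lines = bifurcation_lines()
    for i in range(len(nu_grid) - 1):
        if keys[i] == keys[i + 1]:
            continue
        entry = {"nu_lo": float(nu_grid[i]), "nu_hi": float(nu_grid[i + 1]),
                 "line": None, "nu_root": None}
        if refine and keys[i][0] and keys[i + 1][0]:
            for ln in lines:
                g = lambda nu: ln.residual(1.0 / nu, kappa)
                if g(nu_grid[i]) * g(nu_grid[i + 1]) <= 0.0:
                    entry["line"] = ln.label
                    try:
                        entry["nu_root"] = detect_transition(
                            g, float(nu_grid[i]), float(nu_grid[i + 1]), 1e-10)
                    except ValueError:  # endpoint zero handled above
                        pass
                    break
        transitions.append(entry)
    return SweepResult("nu", nu_grid, pd.DataFrame(rows), transitions)


# ---------------------------------------------------------------------------
# analytic vs numerical comparison
# ---------------------------------------------------------------------------

def compare_analytic_numeric(param_grid, slow_time_span: float = 80.0,
                             rtol: float = 1e-9) -> pd.DataFrame:
    """Compare predicted and simulated limit-cycle amplitudes.

    For each dimensional parameter set: find the stable equal-amplitude
    catalogue branch, un-scale its amplitudes, simulate the full
    oscillator model from initial data near that state, extract the
    slow flow and record the relative amplitude discrepancy and the
    settled relative phase.  Divergent runs are recorded, not raised.
    Agreement is quantitative in the weakly damped regime
    (gamma << omega) and qualitative at larger amplitudes.
    """
    out = []
    for params in param_grid:
        rec = {"gamma": params.gamma, "a": params.a, "b": params.b,
               "omega": params.omega, "branch": "none",
               "r_pred": np.nan, "r_sim": np.nan,
               "phi_pred": np.nan, "phi_sim": np.nan,
               "rel_discrepancy": np.nan, "status": "ok"}
        hopf = hopf_amplitude_inphase(params)
        if hopf.exists and hopf.amplitude == 0.0:
            rec["branch"], rec["status"] = "HB_I", "no oscillation"
            rec["r_pred"] = 0.0
            out.append(rec)
            continue
        try:
            ndp = to_mu_kappa(params)
        except ZeroDivisionError:
            rec["status"] = "mu/kappa undefined"
            out.append(rec)
            continue
        if ndp.s_gamma != 1 or ndp.s_delta != 1:
            rec["status"] = "outside ++ sign regime"
            out.append(rec)
            continue
        stable_br = None
        for label in ("I", "A", "L+"):
            br = branch_value(label, ndp.mu, ndp.kappa)
            if br.exists and br.stable is True:
                stable_br = br
                break
        if stable_br is None:
            rec["status"] = "no stable equal-amplitude branch"
            out.append(rec)
            continue
        r1, r2, phi = dimensionalize_steady_state(stable_br, params)
        rec["branch"], rec["r_pred"], rec["phi_pred"] = stable_br.label, r1, phi
        w = params.omega
        y0 = [r1 * math.cos(phi) * 1.02, r2 * 0.98,
              -r1 * w * math.sin(phi) * 1.02, 0.0]
        t_end = 2.0 * slow_time_span / abs(params.gamma)
        traj = integrate("full", params, y0, t_end, rtol=rtol, atol=1e-11)
        if traj.diverged:
            rec["status"] = "diverged"
            out.append(rec)
            continue
        sf = extract_slow_flow(traj, omega=w)
        tail = sf.times >= sf.times[0] + 0.9 * (sf.times[-1] - sf.times[0])
        r_sim = float(np.mean(sf.r1[tail]))
        rec["r_sim"] = r_sim
        rec["phi_sim"] = float(np.angle(np.mean(np.exp(1j * sf.phi[tail]))))
        rec["rel_discrepancy"] = abs(r_sim - r1) / r1
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# literature fixtures
# ---------------------------------------------------------------------------

def _avitabile(a_sign: float, b_sign: float, gamma: float = 1.0) -> HKBParams:
    return HKBParams(gamma=gamma, alpha=1.0, beta=1.0, a=0.5 * a_sign,
                     b=0.5 * b_sign, c=0.0, omega=2.0)


def fixtures() -> dict:
    """Named parameter sets from the coordination-dynamics literature plus
    canonical (kappa, mu) test points, one per qualitative region.

    The ``avitabile_*`` sets (alpha = beta = 1, a = +-0.5, b = +-0.5,
    c = 0, omega = 2) give sigma = +-26 and were studied with gamma swept
    over [-2, 8]; gamma defaults to 1 here.  ``leise_cohen`` ships the
    published damping/coupling values with omega = 1 and c = 0 (neither
    is tabulated with the set).  ``slowinski`` has a free in [-15, 15] in
    the source; a = 1 and omega = 2 are shipped as a representative
    point.  (kappa, mu) entries are dicts with keys ``kappa``/``mu``.
    """
    return {
        "avitabile_pp": _avitabile(+1, +1),
        "avitabile_pm": _avitabile(+1, -1),
        "avitabile_mp": _avitabile(-1, +1),
        "avitabile_mm": _avitabile(-1, -1),
        "leise_cohen": HKBParams(gamma=0.5, alpha=0.38, beta=0.001,
                                 a=-0.05, b=0.036, c=0.0, omega=1.0),
        "slowinski": HKBParams(gamma=0.64, alpha=112.457, beta=0.008,
                               a=1.0, b=1.0, c=0.0, omega=2.0),
        # canonical (kappa, mu) points, one per qualitative region
        "stable_I_point": {"kappa": 0.05, "mu": -0.3},     # I stable alone
        "stable_A_point": {"kappa": 0.05, "mu": 0.3},      # A stable, I not
        "bistable_point": {"kappa": 0.1, "mu": -0.2},      # I and A stable
        "lag90_point": {"kappa": -0.5, "mu": 1.0},         # L+- at 90 degrees
        "N_region_point": {"kappa": 0.5, "mu": 0.5},       # N0 branches exist
        "triple_point": {"kappa": -1.0, "mu": 1.0},        # BP_N/BP_II/BP_AA
    }


def fixture(name: str):
    """Look up a single named fixture; raises ``KeyError`` for unknown names."""
    table = fixtures()
    if name not in table:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(table)}")
    return table[name]
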