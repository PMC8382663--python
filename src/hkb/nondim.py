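"""Averaged (slow-flow) HKB equations and their nondimensional forms.

Averaging the weakly damped, weakly coupled HKB model over the fast
oscillation at pacing frequency ``omega`` yields a three-dimensional slow
flow for the two amplitudes and the relative phase ``phi = phi1 - phi2``
(the aHKB model).  Rescaling amplitudes by the in-phase limit-cycle
radius and time by half the linear damping reduces that flow to a system
governed by just two dimensionless parameters,

    mu = a / gamma          (linear coupling over linear damping)
    kappa = d / delta       (combined nonlinear coupling over damping),

with reciprocal parameterisation nu = 1/mu, sigma = 1/kappa better
suited to sweeps through gamma = 0.  Sign-generalised forms carry the
signs of gamma and delta (or of a and d) explicitly so that arbitrary
parameter quadrants can be explored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import HKBParams, combined_coeffs

__all__ = [
    "GUARD_RADIUS",
    "AmplitudeGuardError",
    "NondimParams",
    "AltNondimParams",
    "PolarState",
    "ScaleFactors",
    "to_mu_kappa",
    "to_nu_sigma",
    "ahkb_rhs_dimensional",
    "ahkb_rhs_nondim",
    "ahkb_rhs_alt",
    "scale_factors",
    "dimensionalize_steady_state",
    "wrap_phase",
]

#: Minimum amplitude below which the polar phase equation is treated as
#: singular; trajectories entering this guard are classified as collapsing
#: onto the degenerate zero-amplitude (Z) family.
GUARD_RADIUS = 1e-6


class AmplitudeGuardError(ValueError):
    """Raised when a polar slow-flow evaluation is requested below the
    amplitude guard radius, where the relative phase is ill-defined."""


def wrap_phase(phi: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    w = math.remainder(phi, 2.0 * math.pi)  # in [-pi, pi]
    return w if w != -math.pi else math.pi


@dataclass(frozen=True)
class NondimParams:
    """Dimensionless parameters (mu, kappa) with the signs of gamma and
    of the combined nonlinear damping delta.

    With ``s_gamma = s_delta = +1`` the slow flow takes the canonical
    form used for the steady-state catalogue; other sign combinations
    use the sign-generalised vector field.
    """

    mu: float
    kappa: float
    s_gamma: int = 1
    s_delta: int = 1

    def __post_init__(self):
        if self.s_gamma not in (1, -1) or self.s_delta not in (1, -1):
            raise ValueError("sign flags must be +1 or -1")


@dataclass(frozen=True)
class AltNondimParams:
    """Reciprocal dimensionless parameters (nu, sigma) = (1/mu, 1/kappa)
    with the signs of a and of the combined nonlinear coupling d."""

    nu: float
    sigma: float
    s_a: int = 1
    s_d: int = 1

    def __post_init__(self):
        if self.s_a not in (1, -1) or self.s_d not in (1, -1):
            raise ValueError("sign flags must be +1 or -1")


@dataclass(frozen=True)
class PolarState:
    """Slow-flow state: nondimensional amplitudes and relative phase."""

    R1: float
    R2: float
    phi: float

    def __post_init__(self):
        if self.R1 < 0 or self.R2 < 0:
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "phi", wrap_phase(self.phi))

    def as_array(self) -> np.ndarray:
        return np.array([self.R1, self.R2, self.phi])


@dataclass(frozen=True)
class ScaleFactors:
    """Amplitude scale r_scale [L] and time dilation t_scale [1/T].

    Slow time is ``s = t_scale * t``; nondimensional amplitudes are
    ``R_i = r_i / r_scale``.
    """

    r_scale: float
    t_scale: float

    def __post_init__(self):
        if not (self.r_scale > 0 and self.t_scale > 0):
            raise ValueError("scale factors must be positive")


def to_mu_kappa(params: HKBParams) -> NondimParams:
    """Compute mu = a/gamma and kappa = d/delta from dimensional parameters.

    mu is invariant under (a, gamma) -> (k a, k gamma) for any k != 0,
    which is why a single (mu, kappa) point stands for a whole family of
    dimensional models.
    """
    if params.gamma == 0.0:
        raise ZeroDivisionError("mu undefined: linear damping gamma is zero "
                                "(use the (nu, sigma) parameterisation)")
    cc = combined_coeffs(params)
    if cc.delta == 0.0:
        raise ZeroDivisionError("kappa undefined: combined nonlinear damping "
                                "delta = (alpha + 3 beta omega^2)/4 is zero")
    return NondimParams(
        mu=params.a / params.gamma,
        kappa=cc.d / cc.delta,
        s_gamma=1 if params.gamma > 0 else -1,
        s_delta=1 if cc.delta > 0 else -1,
    )


def to_nu_sigma(params: HKBParams) -> AltNondimParams:
    """Compute nu = gamma/a and sigma = delta/d from dimensional parameters."""
    if params.a == 0.0:
        raise ZeroDivisionError("nu undefined: linear coupling a is zero "
                                "(use the (mu, kappa) parameterisation)")
    cc = combined_coeffs(params)
    if cc.d == 0.0:
        raise ZeroDivisionError("sigma undefined: combined nonlinear coupling "
                                "d = (b + 3 c omega^2)/4 is zero")
    return AltNondimParams(
        nu=params.gamma / params.a,
        sigma=cc.delta / cc.d,
        s_a=1 if params.a > 0 else -1,
        s_d=1 if cc.d > 0 else -1,
    )


def _guard(r1: float, r2: float) -> None:
    if r1 < GUARD_RADIUS or r2 < GUARD_RADIUS:
        raise AmplitudeGuardError(
            f"amplitude below guard radius {GUARD_RADIUS}: ({r1}, {r2}); "
            "relative phase is ill-defined (degenerate Z family)")


def ahkb_rhs_dimensional(r1: float, r2: float, phi: float,
                         params: HKBParams) -> tuple[float, float, float]:
    """Dimensional averaged slow flow (dr1/dt, dr2/dt, dphi/dt).

    8 r1' = [4 gamma - (alpha+3 beta w^2) r1^2] r1
            + [4 a + (b+3 c w^2) S] (r1 - r2 cos phi),
    with S = r1^2 + r2^2 - 2 r1 r2 cos phi, and symmetrically for r2;
    8 r1 r2 phi' = (r1^2 + r2^2) sin phi [4 a + (b+3 c w^2) S].
    """
    _guard(r1, r2)
    p = params
    w2 = p.omega**2
    D = p.alpha + 3.0 * p.beta * w2       # 4*delta
    B = p.b + 3.0 * p.c * w2              # 4*d
    cphi = math.cos(phi)
    S = r1 * r1 + r2 * r2 - 2.0 * r1 * r2 * cphi
    coup = 4.0 * p.a + B * S
    dr1 = ((4.0 * p.gamma - D * r1 * r1) * r1 + coup * (r1 - r2 * cphi)) / 8.0
    dr2 = ((4.0 * p.gamma - D * r2 * r2) * r2 + coup * (r2 - r1 * cphi)) / 8.0
    dphi = (r1 * r1 + r2 * r2) * math.sin(phi) * coup / (8.0 * r1 * r2)
    return (dr1, dr2, dphi)


def _polar(state) -> tuple[float, float, float]:
    if isinstance(state, PolarState):
        return state.R1, state.R2, state.phi
    R1, R2, phi = np.asarray(state, dtype=float)
    return float(R1), float(R2), float(phi)


def ahkb_rhs_nondim(state, p: NondimParams,
                    _guarded: bool = True) -> tuple[float, float, float]:
    """Sign-generalised nondimensional slow flow (dR1/ds, dR2/ds, dphi/ds).

    With s_gamma = s_delta = +1 this is the canonical two-parameter form

        R1' = R1 - R1^3 + (R1 - R2 cos phi)(mu + kappa S),
        R1 R2 phi' = (R1^2 + R2^2) sin phi (mu + kappa S),

    S = R1^2 + R2^2 - 2 R1 R2 cos phi.  General signs replace the linear
    terms by (s_gamma - s_delta R^2) R and the bracket by
    (s_gamma mu + s_delta kappa S).
    """
    R1, R2, phi = _polar(state)
    if _guarded:
        _guard(R1, R2)
    cphi = math.cos(phi)
    S = R1 * R1 + R2 * R2 - 2.0 * R1 * R2 * cphi
    q = p.s_gamma * p.mu + p.s_delta * p.kappa * S
    dR1 = (p.s_gamma - p.s_delta * R1 * R1) * R1 + (R1 - R2 * cphi) * q
    dR2 = (p.s_gamma - p.s_delta * R2 * R2) * R2 + (R2 - R1 * cphi) * q
    denom = max(R1 * R2, GUARD_RADIUS**2)
    dphi = (R1 * R1 + R2 * R2) * math.sin(phi) * q / denom
    return (dR1, dR2, dphi)


def ahkb_rhs_alt(state, p: AltNondimParams,
                 _guarded: bool = True) -> tuple[float, float, float]:
    """Alternative nondimensional slow flow in (nu, sigma):

        R1' = (s_a nu - s_d sigma R1^2) R1 + (R1 - R2 cos phi)(s_a + s_d S),
        R1 R2 phi' = (R1^2 + R2^2) sin phi (s_a + s_d S).

    Time here is s_tilde = |a| t / 2 and amplitudes are scaled by
    sqrt(a/d); trajectories coincide with the (mu, kappa) flow after the
    corresponding rescaling.
    """
    R1, R2, phi = _polar(state)
    if _guarded:
        _guard(R1, R2)
    cphi = math.cos(phi)
    S = R1 * R1 + R2 * R2 - 2.0 * R1 * R2 * cphi
    q = p.s_a + p.s_d * S
    dR1 = (p.s_a * p.nu - p.s_d * p.sigma * R1 * R1) * R1 + (R1 - R2 * cphi) * q
    dR2 = (p.s_a * p.nu - p.s_d * p.sigma * R2 * R2) * R2 + (R2 - R1 * cphi) * q
    denom = max(R1 * R2, GUARD_RADIUS**2)
    dphi = (R1 * R1 + R2 * R2) * math.sin(phi) * q / denom
    return (dR1, dR2, dphi)


def scale_factors(params: HKBParams, convention: str = "signed") -> ScaleFactors:
    """Amplitude/time scales linking the dimensional and nondimensional flows.

    Conventions
    -----------
    ``"mu_kappa"``
        r_scale = 2*sqrt(gamma/(alpha+3 beta w^2)) = sqrt(gamma/delta),
        slow time s = (gamma/2) t.  Requires gamma > 0 and gamma/delta > 0.
    ``"signed"`` (default)
        r_scale = sqrt(|gamma/delta|), s = (|gamma|/2) t; defined for any
        nonzero gamma, delta.
    ``"alt"``
        r_scale = sqrt(a/d), s_tilde = (|a|/2) t.  Requires a/d > 0 (the
        printed scale is real only in that case).
    """
    cc = combined_coeffs(params)
    if convention == "mu_kappa":
        if params.gamma <= 0:
            raise ValueError("mu_kappa convention requires gamma > 0 "
                             "(use convention='signed')")
        if cc.delta <= 0:
            raise ValueError("mu_kappa convention requires delta > 0 "
                             "(use convention='signed')")
        return ScaleFactors(math.sqrt(params.gamma / cc.delta), params.gamma / 2.0)
    if convention == "signed":
        if params.gamma == 0 or cc.delta == 0:
            raise ZeroDivisionError("signed scales undefined for gamma=0 or delta=0")
        return ScaleFactors(math.sqrt(abs(params.gamma / cc.delta)),
                            abs(params.gamma) / 2.0)
    if convention == "alt":
        if cc.d == 0 or params.a == 0:
            raise ZeroDivisionError("alt scales undefined for a=0 or d=0")
        if params.a / cc.d <= 0:
            raise ValueError("alt amplitude scale sqrt(a/d) undefined for a/d < 0")
        return ScaleFactors(math.sqrt(params.a / cc.d), abs(params.a) / 2.0)
    raise ValueError(f"unknown convention {convention!r}")


def dimensionalize_steady_state(branch, params: HKBParams,
                                convention: str = "signed"
                                ) -> tuple[float, float, float]:
    """Un-scale a catalogue steady state to physical amplitudes.

    Returns ``(r1*, r2*, phi*)`` with ``r_i* = r_scale * R_i*``.  The
    degenerate Z branches map to zero amplitude.  Raises ``ValueError``
    if the branch does not exist at the (mu, kappa) implied by params.
    """
    if not branch.exists:
        raise ValueError(f"branch {branch.label} does not exist at the given "
                         "(mu, kappa); cannot dimensionalize")
    sf = scale_factors(params, convention)
    return (sf.r_scale * branch.R1_star, sf.r_scale * branch.R2_star,
            branch.phi_star)
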