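"""Dimensional Haken-Kelso-Bunz (HKB) oscillator equations.

The full HKB model couples two hybrid Rayleigh/van der Pol oscillators

    x1'' + w^2 x1 = (gamma - alpha x1^2 - beta x1'^2) x1'
                    + [a + b (x1-x2)^2 + c (x1'-x2')^2] (x1' - x2'),

and symmetrically for x2.  This module evaluates the full and linear
right-hand sides, the normal-mode (in-phase/anti-phase) decomposition of
the linear model, the combined nonlinear coefficients

    delta = (alpha + 3 beta w^2)/4,   d = (b + 3 c w^2)/4,

and the weakly nonlinear Hopf limit-cycle amplitudes of the in-phase and
anti-phase synchronised motions.

State ordering is fixed as ``(x1, x2, v1, v2)`` throughout the package,
where ``v_i = dx_i/dt``.
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, asdict

import numpy as np
import yaml

__all__ = [
    "STATE_ORDER",
    "HKBParams",
    "OscillatorState",
    "NormalModeCoeffs",
    "CombinedCoeffs",
    "HopfResult",
    "full_hkb_rhs",
    "linear_hkb_rhs",
    "normal_mode_transform",
    "normal_mode_coeffs",
    "mode_eigenvalues",
    "classify_linear_regions",
    "combined_coeffs",
    "hopf_amplitude_inphase",
    "hopf_amplitude_antiphase",
]

#: Fixed ordering of the 4-dimensional oscillator state.
STATE_ORDER = ("x1", "x2", "v1", "v2")

_PARAM_KEYS = ("gamma", "alpha", "beta", "a", "b", "c", "omega", "epsilon")


@dataclass(frozen=True)
class HKBParams:
    """Dimensional coefficients of the full HKB model.

    Parameters
    ----------
    gamma : float
        Linear damping coefficient, units 1/T.  Positive values pump
        energy into the motion (negative damping).
    alpha : float
        Van der Pol (position-dependent) damping coefficient, 1/(L^2 T).
    beta : float
        Rayleigh (velocity-dependent) damping coefficient, T/L^2.
    a : float
        Linear coupling coefficient, 1/T.
    b, c : float
        Nonlinear coupling coefficients, 1/(L^2 T) and T/L^2.
    omega : float
        Pacing (control) frequency, 1/T; strictly positive.
    epsilon : float, optional
        Smallness bookkeeping multiplier on the whole damping+coupling
        bracket.  Default 1.  "Weak" regimes are normally produced by
        choosing small coefficient magnitudes rather than epsilon < 1.
    """

    gamma: float
    alpha: float
    beta: float
    a: float
    b: float
    c: float
    omega: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        vals = [getattr(self, k) for k in _PARAM_KEYS]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("HKBParams entries must be finite")
        if self.omega <= 0:
            raise ValueError(f"pacing frequency omega must be > 0, got {self.omega}")

    # -- flat key/value (de)serialisation --------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HKBParams":
        unknown = set(d) - set(_PARAM_KEYS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "HKBParams":
        """Load from a flat YAML or JSON mapping (keys gamma..epsilon)."""
        path = pathlib.Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class OscillatorState:
    """Full-model state: displacements, velocities and time."""

    x1: float
    x2: float
    v1: float
    v2: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.v1, self.v2], dtype=float)

    @classmethod
    def from_array(cls, y, t: float = 0.0) -> "OscillatorState":
        x1, x2, v1, v2 = np.asarray(y, dtype=float)
        return cls(x1, x2, v1, v2, t)


@dataclass(frozen=True)
class NormalModeCoeffs:
    """Effective damping of the two normal modes of the linear model.

    The in-phase mode eta_I = x1 + x2 obeys eta'' - gamma eta' + w^2 eta = 0
    and the anti-phase mode eta_A = x1 - x2 obeys
    eta'' - (2a + gamma) eta' + w^2 eta = 0, so ``damping_I = gamma`` and
    ``damping_A = 2a + gamma`` (a positive "damping" here destabilises).
    """

    damping_I: float
    damping_A: float
    omega: float


@dataclass(frozen=True)
class CombinedCoeffs:
    """Averaged nonlinear coefficients at pacing frequency omega:
    delta = (alpha + 3 beta w^2)/4 (damping), d = (b + 3 c w^2)/4 (coupling)."""

    delta: float
    d: float


@dataclass(frozen=True)
class HopfResult:
    """Weakly nonlinear limit-cycle amplitude at a Hopf bifurcation.

    ``amplitude`` is None when no limit cycle exists at the given
    parameters (negative amplitude ratio) or the branch is degenerate.
    ``criticality`` is one of ``supercritical``, ``subcritical``,
    ``degenerate``.
    """

    amplitude: float | None
    criticality: str
    exists: bool
    note: str = ""


def _as_state(state) -> np.ndarray:
    if isinstance(state, OscillatorState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    if y.shape != (4,):
        raise ValueError(f"state must have 4 entries {STATE_ORDER}, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite oscillator state (divergence?)")
    return y


def full_hkb_rhs(state, params: HKBParams) -> np.ndarray:
    """Right-hand side of the full HKB model.

    Returns ``(dx1, dx2, dv1, dv2)``.  The epsilon bookkeeping factor
    multiplies the entire damping+coupling bracket.
    """
    x1, x2, v1, v2 = _as_state(state)
    p = params
    dv = v1 - v2
    dx = x1 - x2
    coup = p.a + p.b * dx * dx + p.c * dv * dv
    dv1 = -p.omega**2 * x1 + p.epsilon * (
        (p.gamma - p.alpha * x1 * x1 - p.beta * v1 * v1) * v1 + coup * dv
    )
    dv2 = -p.omega**2 * x2 + p.epsilon * (
        (p.gamma - p.alpha * x2 * x2 - p.beta * v2 * v2) * v2 - coup * dv
    )
    return np.array([v1, v2, dv1, dv2])


def linear_hkb_rhs(state, params: HKBParams) -> np.ndarray:
    """Right-hand side of the linear HKB model (nonlinear terms dropped)."""
    x1, x2, v1, v2 = _as_state(state)
    p = params
    dv = v1 - v2
    dv1 = -p.omega**2 * x1 + p.epsilon * (p.gamma * v1 + p.a * dv)
    dv2 = -p.omega**2 * x2 + p.epsilon * (p.gamma * v2 - p.a * dv)
    return np.array([v1, v2, dv1, dv2])


def normal_mode_transform(state) -> np.ndarray:
    """Map an oscillator state to normal-mode coordinates.

    Returns ``(eta_I, deta_I, eta_A, deta_A)`` with eta_I = x1 + x2
    (in-phase) and eta_A = x1 - x2 (anti-phase).  The map is linear and
    invertible.
    """
    x1, x2, v1, v2 = _as_state(state)
    return np.array([x1 + x2, v1 + v2, x1 - x2, v1 - v2])


def normal_mode_coeffs(params: HKBParams) -> NormalModeCoeffs:
    """Effective dampings (gamma, 2a+gamma) of the two normal modes."""
    return NormalModeCoeffs(
        damping_I=params.gamma,
        damping_A=2.0 * params.a + params.gamma,
        omega=params.omega,
    )


def mode_eigenvalues(damping: float, omega: float) -> tuple[complex, complex]:
    """Roots of the mode equation lambda^2 - damping*lambda + omega^2 = 0."""
    disc = complex(damping * damping - 4.0 * omega * omega)
    root = np.sqrt(disc)
    return ((damping + root) / 2.0, (damping - root) / 2.0)


def classify_linear_regions(gamma: float, a: float, boundary_tol: float = 1e-9) -> str:
    """Classify a point of the (gamma, a) plane of the linear model.

    The in-phase mode is unstable for gamma > 0 and the anti-phase mode
    for 2a + gamma > 0.  Returns one of ``"I-unstable"``, ``"A-unstable"``,
    ``"both-unstable"``, ``"S"`` (all oscillations decay), or a
    ``"boundary(<label>/<label>)"`` string listing the adjacent regions
    when the point lies (within ``boundary_tol``) on gamma = 0 (the line
    HB_I) or 2a + gamma = 0 (the line HB_A).
    """
    dA = 2.0 * a + gamma
    on_I = abs(gamma) <= boundary_tol
    on_A = abs(dA) <= boundary_tol

    def label(g_sign: int, dA_sign: int) -> str:
        if g_sign > 0 and dA_sign > 0:
            return "both-unstable"
        if g_sign > 0:
            return "I-unstable"
        if dA_sign > 0:
            return "A-unstable"
        return "S"

    if not on_I and not on_A:
        return label(1 if gamma > 0 else -1, 1 if dA > 0 else -1)

    g_signs = (1, -1) if on_I else ((1,) if gamma > 0 else (-1,))
    a_signs = (1, -1) if on_A else ((1,) if dA > 0 else (-1,))
    adjacent = sorted({label(gs, as_) for gs in g_signs for as_ in a_signs})
    return "boundary(" + "/".join(adjacent) + ")"


def combined_coeffs(params: HKBParams) -> CombinedCoeffs:
    """Combined nonlinear damping delta and coupling d at frequency omega."""
    w2 = params.omega**2
    return CombinedCoeffs(
        delta=0.25 * (params.alpha + 3.0 * params.beta * w2),
        d=0.25 * (params.b + 3.0 * params.c * w2),
    )


def _hopf(num: float, den: float, num_name: str) -> HopfResult:
    if den == 0.0:
        return HopfResult(None, "degenerate", False,
                          note="zero combined nonlinear damping; amplitude undefined")
    crit = "supercritical" if den > 0 else "subcritical"
    ratio = num / den
    if ratio < 0:
        return HopfResult(None, crit, False,
                          note=f"no limit cycle: {num_name}/denominator < 0")
    return HopfResult(2.0 * math.sqrt(ratio), crit, True)


def hopf_amplitude_inphase(params: HKBParams) -> HopfResult:
    """In-phase limit-cycle amplitude r_I = 2*sqrt(gamma/(alpha+3 beta w^2)).

    A Hopf bifurcation of the in-phase mode occurs at gamma = 0; the
    branch is supercritical (subcritical) for alpha + 3 beta w^2 > 0 (< 0)
    and degenerate when that combination vanishes.
    """
    den = params.alpha + 3.0 * params.beta * params.omega**2
    return _hopf(params.gamma, den, "gamma")


def hopf_amplitude_antiphase(params: HKBParams) -> HopfResult:
    """Anti-phase amplitude r_A = 2*sqrt((gamma+2a)/((alpha+3bw^2)-8(b+3cw^2))).

    The anti-phase Hopf bifurcation occurs at gamma + 2a = 0; the
    denominator equals 4*(delta - 8 d) in terms of the combined
    coefficients and its sign sets the criticality.
    """
    w2 = params.omega**2
    den = (params.alpha + 3.0 * params.beta * w2) - 8.0 * (params.b + 3.0 * params.c * w2)
    return _hopf(params.gamma + 2.0 * params.a, den, "gamma+2a")
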