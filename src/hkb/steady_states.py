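"""Closed-form steady states of the nondimensional averaged HKB flow.

Steady states of the two-parameter slow flow correspond to limit cycles
of the full HKB model.  The catalogue comprises:

* equal-amplitude branches ``I`` (in-phase, (1,1,0)), ``A`` (anti-phase,
  amplitude sqrt((1+2 mu)/(1-8 kappa))) and the phase-lagged pair
  ``L+``/``L-`` with phase +-arccos(1 + mu/(2 kappa));
* unequal-amplitude branches ``N0+/-`` (in-phase), ``Npi+/-``
  (anti-phase) and ``Nhalfpi1/2`` (quarter-period lag, existing only on
  the line mu + kappa = 0), all unstable wherever they exist;
* the degenerate zero-amplitude family ``Z0``, ``Zpi``, ``Zphi``.

Analytic eigenvalues are available for I, A and L+-; a finite-difference
Jacobian serves as an independent oracle and as the only stability
decision procedure in sign-generalised regimes.  Bifurcation lines
HB_A, BP_AL, BP_II, BP_AA and BP_N organise the (kappa, mu) plane.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import HKBParams
from .nondim import GUARD_RADIUS, NondimParams, ahkb_rhs_nondim, wrap_phase

__all__ = [
    "LINE_TOL",
    "EQUAL_AMPLITUDE_BRANCHES",
    "UNEQUAL_AMPLITUDE_BRANCHES",
    "DEGENERATE_BRANCHES",
    "MAIN_BRANCHES",
    "ALL_BRANCHES",
    "SteadyStateBranch",
    "BifurcationLine",
    "BistabilityVerdict",
    "NotASteadyStateError",
    "SingularBranchError",
    "branch_value",
    "existence",
    "on_existence_boundary",
    "eigenvalues_I",
    "eigenvalues_A",
    "eigenvalues_L",
    "numerical_jacobian_eigs",
    "bifurcation_lines",
    "hb_i_dimensional",
    "hb_a_dimensional",
    "triple_intersection",
    "stability_chart",
    "bistability_region_dimensional",
    "phase_lag_line",
]

#: Points within this distance of a bifurcation/existence line are treated
#: as lying on it (the qualitative transitions live on these sets).
LINE_TOL = 1e-9

EQUAL_AMPLITUDE_BRANCHES = ("I", "A", "L+", "L-")
UNEQUAL_AMPLITUDE_BRANCHES = ("N0+", "N0-", "Npi+", "Npi-", "Nhalfpi1", "Nhalfpi2")
DEGENERATE_BRANCHES = ("Z0", "Zpi", "Zphi")
#: Branches plotted on the stability/instability charts.
MAIN_BRANCHES = ("I", "A", "L+", "L-", "N0+", "N0-", "Npi+", "Npi-")
ALL_BRANCHES = EQUAL_AMPLITUDE_BRANCHES + UNEQUAL_AMPLITUDE_BRANCHES + DEGENERATE_BRANCHES


class NotASteadyStateError(ValueError):
    """The supplied state does not satisfy the steady-state residual."""


class SingularBranchError(ZeroDivisionError):
    """Closed-form branch data undefined at this parameter point."""


@dataclass(frozen=True)
class SteadyStateBranch:
    """One catalogue entry evaluated at a (mu, kappa) point."""

    label: str
    R1_star: float
    R2_star: float
    phi_star: float
    exists: bool
    boundary: bool = False
    eigenvalues: tuple = ()
    stable: object = None  # True / False / "marginal" / "degenerate"


@dataclass(frozen=True)
class BifurcationLine:
    """Affine line c_mu * mu + c_kappa * kappa + c_0 = 0 in the (kappa, mu)
    plane."""

    label: str
    c_mu: float
    c_kappa: float
    c_0: float

    def residual(self, mu: float, kappa: float) -> float:
        return self.c_mu * mu + self.c_kappa * kappa + self.c_0

    def contains(self, mu: float, kappa: float, tol: float = LINE_TOL) -> bool:
        return abs(self.residual(mu, kappa)) <= tol


@dataclass(frozen=True)
class BistabilityVerdict:
    """Outcome of the dimensional bistability test; truthy iff bistable."""

    bistable: bool
    on_boundary: bool

    def __bool__(self) -> bool:
        return self.bistable


# ---------------------------------------------------------------------------
# existence predicates (Table of steady states)
# ---------------------------------------------------------------------------

def _exists_strict(label: str, mu: float, kappa: float) -> bool:
    if label in ("I", "Z0", "Zpi"):
        return True
    if label == "A":
        return (kappa < 0.125 and mu > -0.5) or (kappa > 0.125 and mu < -0.5)
    if label in ("L+", "L-"):
        return (0.0 < mu < -4.0 * kappa) or (-4.0 * kappa < mu < 0.0)
    if label in ("N0+", "N0-"):
        return ((kappa < -1.0 and mu > 1.0 and mu + kappa < 0.0)
                or (kappa > -1.0 and mu < 1.0 and mu + kappa > 0.0))
    if label in ("Npi+", "Npi-"):
        return ((kappa < -1.0 and 3.0 * mu + 4.0 * kappa + 1.0 < 0.0 and mu + kappa > 0.0)
                or (kappa > -1.0 and 3.0 * mu + 4.0 * kappa + 1.0 > 0.0 and mu + kappa < 0.0))
    if label in ("Nhalfpi1", "Nhalfpi2"):
        return abs(mu + kappa) <= LINE_TOL
    if label == "Zphi":
        return abs(mu) <= LINE_TOL
    raise KeyError(f"unknown branch label {label!r}")


def _boundary_exprs(label: str, mu: float, kappa: float) -> list[float]:
    """Expressions whose zeros bound the existence region of `label`."""
    if label == "A":
        return [kappa - 0.125, mu + 0.5]
    if label in ("L+", "L-"):
        return [mu, mu + 4.0 * kappa]
    if label in ("N0+", "N0-"):
        return [kappa + 1.0, mu - 1.0, mu + kappa]
    if label in ("Npi+", "Npi-"):
        return [kappa + 1.0, 3.0 * mu + 4.0 * kappa + 1.0, mu + kappa]
    return []


def existence(label: str, mu: float, kappa: float) -> bool:
    """Strict-inequality existence predicate for a catalogue branch."""
    return _exists_strict(label, mu, kappa)


def on_existence_boundary(label: str, mu: float, kappa: float,
                          tol: float = LINE_TOL) -> bool:
    """True when (mu, kappa) lies within tol of an existence-region edge."""
    if label in ("Nhalfpi1", "Nhalfpi2", "Zphi"):
        return _exists_strict(label, mu, kappa)  # measure-zero existence sets
    return any(abs(e) <= tol for e in _boundary_exprs(label, mu, kappa))


# ---------------------------------------------------------------------------
# analytic eigenvalues of the equal-amplitude branches
# ---------------------------------------------------------------------------

def eigenvalues_I(mu: float) -> tuple[float, float, float]:
    """Eigenvalues at the in-phase branch: (-2, 2(mu-1), 2 mu).

    I is stable for mu < 0 and unstable for mu > 0; the first eigenvalue
    is constant in both parameters.
    """
    return (-2.0, 2.0 * (mu - 1.0), 2.0 * mu)


def eigenvalues_A(mu: float, kappa: float) -> tuple[float, float, float]:
    """Eigenvalues at the anti-phase branch:

    (-2(1+2 mu), 2(1+3 mu+4 kappa)/(8 kappa-1), 2(mu+4 kappa)/(8 kappa-1)).

    The first vanishes on HB_A (mu = -1/2), the third on BP_AL
    (mu + 4 kappa = 0); the shared denominator is singular on the
    amplitude pole kappa = 1/8.
    """
    if abs(8.0 * kappa - 1.0) <= LINE_TOL:
        raise SingularBranchError("branch A eigenvalues singular at kappa = 1/8")
    den = 8.0 * kappa - 1.0
    return (-2.0 * (1.0 + 2.0 * mu),
            2.0 * (1.0 + 3.0 * mu + 4.0 * kappa) / den,
            2.0 * (mu + 4.0 * kappa) / den)


def eigenvalues_L(mu: float, kappa: float) -> tuple[complex, complex, float]:
    """Eigenvalues at the phase-lagged branches:

    -(1+2 mu) +- f(kappa, mu) and -2, with
    f = sqrt(kappa^4 (2 mu-1)^2 - 2 kappa^3 mu^2) / kappa^2 (possibly
    complex).  L+- is stable between mu = 0 and mu + 4 kappa = 0 for
    kappa < 0 and unstable between the same lines for kappa > 0.
    """
    if kappa == 0.0:
        raise SingularBranchError("branch L eigenvalues undefined at kappa = 0")
    f = cmath.sqrt(kappa**4 * (2.0 * mu - 1.0) ** 2 - 2.0 * kappa**3 * mu**2) / kappa**2
    lam1 = -(1.0 + 2.0 * mu) + f
    lam2 = -(1.0 + 2.0 * mu) - f
    return (_real_if_close(lam1), _real_if_close(lam2), -2.0)


def _real_if_close(z: complex, tol: float = 1e-13):
    return z.real if abs(z.imag) <= tol * max(1.0, abs(z)) else z


def _verdict(eigs, tol: float = LINE_TOL):
    if not eigs:
        return None
    m = max(complex(e).real for e in eigs)
    if m < -tol:
        return True
    if m > tol:
        return False
    return "marginal"


# ---------------------------------------------------------------------------
# numerical Jacobian oracle
# ---------------------------------------------------------------------------

def numerical_jacobian_eigs(state, p: NondimParams, h: float = 1e-6,
                            residual_tol: float = 1e-10) -> np.ndarray:
    """Eigenvalues of the central-difference Jacobian of the slow flow.

    Serves as the independent oracle for the analytic eigenvalue
    formulas, and as the sole stability decision in sign-generalised
    regimes where no closed forms are printed.  ``state`` must satisfy
    the steady-state residual to within ``residual_tol``.
    """
    y0 = np.asarray(state.as_array() if hasattr(state, "as_array") else state,
                    dtype=float)
    res = np.linalg.norm(ahkb_rhs_nondim(y0, p))
    if res > residual_tol:
        raise NotASteadyStateError(
            f"residual {res:.3e} exceeds {residual_tol:.1e}: not a steady state")
    J = np.empty((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        fp = np.asarray(ahkb_rhs_nondim(y0 + e, p))
        fm = np.asarray(ahkb_rhs_nondim(y0 - e, p))
        J[:, j] = (fp - fm) / (2.0 * h)
    return np.linalg.eigvals(J)


# ---------------------------------------------------------------------------
# branch catalogue
# ---------------------------------------------------------------------------

def _sqrt_or_nan(x: float) -> float:
    return math.sqrt(x) if x >= 0.0 else float("nan")


def _n_radicals(mu: float, kappa: float) -> tuple[float, float]:
    """The two half-radicals shared by the N0 and Npi branches."""
    if abs(1.0 + kappa) <= LINE_TOL:
        return float("nan"), float("nan")
    p = 0.5 * _sqrt_or_nan((1.0 + 3.0 * mu + 4.0 * kappa) / (1.0 + kappa))
    q = 0.5 * _sqrt_or_nan((1.0 - mu) / (1.0 + kappa))
    return p, q


def branch_value(label: str, mu: float, kappa: float,
                 attach_eigenvalues: bool = True) -> SteadyStateBranch:
    """Evaluate one catalogue branch at a (mu, kappa) point.

    Nonexistence is reported through the ``exists`` flag, never raised.
    Analytic eigenvalues are attached for I, A and L+-; the unequal-
    amplitude N branches get finite-difference eigenvalues where their
    amplitudes are positive; the Z family is flagged degenerate.
    """
    if label not in ALL_BRANCHES:
        raise KeyError(f"unknown branch label {label!r}; choose from {ALL_BRANCHES}")
    exists = _exists_strict(label, mu, kappa)
    boundary = on_existence_boundary(label, mu, kappa)
    eigs: tuple = ()
    stable: object = None

    if label == "I":
        R1 = R2 = 1.0
        phi = 0.0
        if attach_eigenvalues:
            eigs = eigenvalues_I(mu)
    elif label == "A":
        amp2 = ((1.0 + 2.0 * mu) / (1.0 - 8.0 * kappa)
                if abs(1.0 - 8.0 * kappa) > LINE_TOL else float("nan"))
        R1 = R2 = _sqrt_or_nan(amp2) if not math.isnan(amp2) else float("nan")
        phi = math.pi
        if attach_eigenvalues and exists:
            eigs = eigenvalues_A(mu, kappa)
    elif label in ("L+", "L-"):
        R1 = R2 = 1.0
        arg = 1.0 + mu / (2.0 * kappa) if kappa != 0.0 else float("nan")
        phi = (math.acos(arg) if -1.0 <= arg <= 1.0 else float("nan"))
        if label == "L-" and not math.isnan(phi):
            phi = -phi
        if attach_eigenvalues and exists:
            eigs = eigenvalues_L(mu, kappa)
    elif label in ("N0+", "N0-", "Npi+", "Npi-"):
        p, q = _n_radicals(mu, kappa)
        sign = 1.0 if label.endswith("+") else -1.0
        if label.startswith("N0"):
            R1, R2, phi = p + sign * q, p - sign * q, 0.0
        else:
            R1, R2, phi = q + sign * p, q - sign * p, math.pi
        if (attach_eigenvalues and exists
                and min(R1, R2) > GUARD_RADIUS and not math.isnan(R1)):
            try:
                eigs = tuple(numerical_jacobian_eigs(
                    np.array([R1, R2, phi]), NondimParams(mu, kappa)))
            except NotASteadyStateError:  # pragma: no cover - defensive
                eigs = ()
    elif label == "Nhalfpi1":
        R1, R2, phi = 1.0, 0.0, math.pi / 2.0
        stable = False if exists else None  # unstable wherever it exists
    elif label == "Nhalfpi2":
        R1, R2, phi = 0.0, 1.0, math.pi / 2.0
        stable = False if exists else None
    else:  # Z family
        R1 = R2 = 0.0
        phi = {"Z0": 0.0, "Zpi": math.pi, "Zphi": float("nan")}[label]
        stable = "degenerate"

    if stable is None:
        stable = _verdict(eigs) if exists else None
    if not math.isnan(phi):
        phi = wrap_phase(phi)
    return SteadyStateBranch(label, R1, R2, phi, exists, boundary, eigs, stable)


# ---------------------------------------------------------------------------
# bifurcation lines and derived geometry
# ---------------------------------------------------------------------------

_LINES = (
    BifurcationLine("HB_A", 1.0, 0.0, 0.5),     # mu = -1/2
    BifurcationLine("BP_AL", 1.0, 4.0, 0.0),    # mu + 4 kappa = 0
    BifurcationLine("BP_II", 1.0, 0.0, -1.0),   # mu = 1
    BifurcationLine("BP_AA", 3.0, 4.0, 1.0),    # 3 mu + 4 kappa + 1 = 0
    BifurcationLine("BP_N", 1.0, 1.0, 0.0),     # mu + kappa = 0
)


def bifurcation_lines() -> tuple[BifurcationLine, ...]:
    """The five analytic bifurcation lines of the (kappa, mu) plane."""
    return _LINES


def hb_i_dimensional(gamma: float, a: float) -> float:
    """Residual of the dimensional in-phase Hopf line HB_I: gamma = 0."""
    return gamma


def hb_a_dimensional(gamma: float, a: float) -> float:
    """Residual of the dimensional anti-phase Hopf line HB_A: 2a + gamma = 0."""
    return 2.0 * a + gamma


def triple_intersection() -> tuple[float, float]:
    """The point where BP_N, BP_II and BP_AA meet.

    Solves the 2x2 linear system from BP_II and BP_AA and verifies that
    BP_N passes through the solution.  Returns ``(kappa, mu)``.
    """
    by_label = {ln.label: ln for ln in _LINES}
    l1, l2, l3 = by_label["BP_II"], by_label["BP_AA"], by_label["BP_N"]
    A = np.array([[l1.c_mu, l1.c_kappa], [l2.c_mu, l2.c_kappa]])
    rhs = -np.array([l1.c_0, l2.c_0])
    mu, kappa = np.linalg.solve(A, rhs)
    if abs(l3.residual(mu, kappa)) > LINE_TOL:
        raise ArithmeticError("BP_N does not pass through the BP_II/BP_AA "
                              "intersection")  # pragma: no cover
    return float(kappa), float(mu)


def phase_lag_line(phi_target: float) -> BifurcationLine:
    """Locus in (kappa, mu) of phase-lagged states with lag ``phi_target``.

    From cos(phi*) = 1 + mu/(2 kappa): mu = 2 kappa (cos(phi_target) - 1),
    i.e. mu + 2 kappa (1 - cos(phi_target)) = 0.  ``phi_target`` must lie
    strictly inside (0, pi); the endpoints degenerate to branches I and A.
    """
    if not 0.0 < phi_target < math.pi:
        raise ValueError(
            "phi_target must lie in the open interval (0, pi); a lag of 0 is "
            "branch I and a lag of pi is branch A (see branch_value)")
    return BifurcationLine(
        f"L-phase-{math.degrees(phi_target):g}deg",
        1.0, 2.0 * (1.0 - math.cos(phi_target)), 0.0)


# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------

def stability_chart(kappa_range=(-2.0, 2.0), mu_range=(-2.0, 2.0),
                    grid_n: int = 50) -> pd.DataFrame:
    """Classify a (kappa, mu) grid by existing and stable branch sets.

    Returns a tidy DataFrame with one row per grid cell and columns
    ``kappa``, ``mu``, ``existing`` and ``stable`` (semicolon-joined
    branch labels).  N branches are unstable wherever they exist.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    kappas = np.linspace(*kappa_range, grid_n)
    mus = np.linspace(*mu_range, grid_n)
    rows = []
    for kappa in kappas:
        for mu in mus:
            existing, stable = [], []
            for label in MAIN_BRANCHES:
                br = branch_value(label, mu, kappa)
                if br.exists:
                    existing.append(label)
                    if br.stable is True:
                        stable.append(label)
            rows.append({"kappa": kappa, "mu": mu,
                         "existing": ";".join(existing),
                         "stable": ";".join(stable)})
    return pd.DataFrame(rows)


def bistability_region_dimensional(params: HKBParams,
                                   tol: float = LINE_TOL) -> BistabilityVerdict:
    """Test whether dimensional couplings put the model in the wedge where
    stable in-phase and anti-phase motion coexist.

    Requires gamma, alpha, beta > 0 (the canonical experimental signs);
    the wedge is a < 0, b < (alpha + 3 beta w^2)/8 and
    a (alpha + 3 beta w^2) + 4 gamma b > 0.  The third expression
    vanishing marks the BP_AL image; that case sets ``on_boundary``.
    """
    if not (params.gamma > 0 and params.alpha > 0 and params.beta > 0):
        raise ValueError(
            "bistability wedge stated for gamma, alpha, beta > 0; for other "
            "signs use the sign-generalised flow and numerical_jacobian_eigs")
    D = params.alpha + 3.0 * params.beta * params.omega**2
    c1 = params.a < 0.0
    c2 = params.b < D / 8.0
    expr3 = params.a * D + 4.0 * params.gamma * params.b
    return BistabilityVerdict(
        bistable=bool(c1 and c2 and expr3 > 0.0),
        on_boundary=bool(c1 and c2 and abs(expr3) <= tol))
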