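"""Tests for the steady-state catalogue, eigenvalues and bifurcation lines."""

import math

import numpy as np
import pytest

from hkb.model_core import HKBParams
from hkb.nondim import NondimParams, ahkb_rhs_nondim
from hkb.steady_states import (
    ALL_BRANCHES,
    MAIN_BRANCHES,
    NotASteadyStateError,
    SingularBranchError,
    bifurcation_lines,
    bistability_region_dimensional,
    branch_value,
    eigenvalues_A,
    eigenvalues_I,
    eigenvalues_L,
    existence,
    hb_a_dimensional,
    hb_i_dimensional,
    numerical_jacobian_eigs,
    phase_lag_line,
    stability_chart,
    triple_intersection,
)

_ckey = lambda z: (z.real, z.imag)


def _sorted(eigs):
    return sorted((complex(e) for e in eigs), key=_ckey)


class TestBranchValues:
    def test_inphase_branch_everywhere(self):
        for mu, kappa in [(0.0, 0.0), (-1.5, 2.0), (3.0, -3.0)]:
            br = branch_value("I", mu, kappa)
            assert (br.R1_star, br.R2_star, br.phi_star) == (1.0, 1.0, 0.0)
            assert br.exists

    def test_antiphase_amplitude(self):
        br = branch_value("A", -0.2, 0.1)
        assert br.R1_star == br.R2_star == pytest.approx(math.sqrt(3), rel=1e-14)
        assert br.phi_star == pytest.approx(math.pi)
        assert br.exists

    def test_lagged_branch_at_quarter_period(self):
        br = branch_value("L+", 1.0, -0.5)
        assert br.exists  # 0 < mu < -4 kappa
        assert br.phi_star == pytest.approx(math.pi / 2, rel=1e-14)
        assert branch_value("L-", 1.0, -0.5).phi_star == pytest.approx(
            -math.pi / 2, rel=1e-14)

    def test_unequal_pairs_are_swap_related(self):
        for plus, minus in [("N0+", "N0-"), ("Npi+", "Npi-")]:
            bp = branch_value(plus, 0.5, 0.5)
            bm = branch_value(minus, 0.5, 0.5)
            assert (bp.R1_star, bp.R2_star) == (bm.R2_star, bm.R1_star)

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            branch_value("Q", 0.0, 0.0)


class TestExistence:
    def test_degenerate_zero_states_exist_everywhere(self):
        for mu, kappa in [(2.0, -2.0), (-0.5, 0.3)]:
            assert existence("Z0", mu, kappa)
            assert existence("Zpi", mu, kappa)

    def test_arbitrary_phase_zero_state_only_at_mu_zero(self):
        assert existence("Zphi", 0.0, 0.7)
        assert not existence("Zphi", 1e-6, 0.7)

    def test_quarter_lag_branches_only_on_bpn_line(self):
        assert existence("Nhalfpi1", 0.5, -0.5)
        assert not existence("Nhalfpi1", 0.5, -0.4)

    def test_antiphase_region_both_cases(self):
        assert existence("A", 0.0, 0.0)           # kappa<1/8, mu>-1/2
        assert existence("A", -1.0, 0.5)          # kappa>1/8, mu<-1/2
        assert not existence("A", -1.0, 0.0)

    def test_boundary_flagged(self):
        br = branch_value("A", -0.5, 0.0)
        assert br.boundary


class TestAnalyticEigenvalues:
    def test_inphase_spectrum(self):
        assert eigenvalues_I(-0.3) == pytest.approx((-2.0, -2.6, -0.6))
        assert eigenvalues_I(0.0)[2] == 0.0          # marginal on HB_A image
        assert eigenvalues_I(0.5)[2] == 1.0 > 0      # unstable for mu > 0

    def test_antiphase_spectrum_in_bistable_wedge(self):
        assert eigenvalues_A(-0.2, 0.1) == pytest.approx((-1.2, -8.0, -2.0))

    def test_antiphase_zero_crossings_on_lines(self):
        assert eigenvalues_A(-0.5, 0.0)[0] == 0.0          # HB_A
        assert eigenvalues_A(-0.4, 0.1)[2] == 0.0          # BP_AL: mu+4kappa=0

    def test_antiphase_singular_at_pole(self):
        with pytest.raises(SingularBranchError):
            eigenvalues_A(0.0, 0.125)

    def test_lagged_spectrum(self):
        l1, l2, l3 = eigenvalues_L(1.0, -0.5)
        assert l3 == -2.0
        f = math.sqrt(0.3125) / 0.25
        assert l1 == pytest.approx(-3.0 + f)
        assert l2 == pytest.approx(-3.0 - f)
        assert max(complex(z).real for z in (l1, l2, l3)) < 0  # stable

    def test_lagged_unstable_for_positive_kappa(self):
        # inside the existence wedge with kappa > 0 at least one
        # eigenvalue is positive
        mu, kappa = -1.0, 0.5  # -4 kappa < mu < 0
        assert existence("L+", mu, kappa)
        assert max(complex(z).real for z in eigenvalues_L(mu, kappa)) > 0

    def test_lagged_undefined_at_kappa_zero(self):
        with pytest.raises(SingularBranchError):
            eigenvalues_L(0.5, 0.0)


class TestNumericalJacobianOracle:
    def test_matches_inphase_formula(self):
        got = _sorted(numerical_jacobian_eigs(
            np.array([1.0, 1.0, 0.0]), NondimParams(-0.3, 0.05)))
        want = _sorted(eigenvalues_I(-0.3))
        assert max(abs(a - b) for a, b in zip(got, want)) < 1e-6

    def test_matches_antiphase_formula(self):
        br = branch_value("A", -0.2, 0.1)
        got = _sorted(numerical_jacobian_eigs(
            np.array([br.R1_star, br.R2_star, br.phi_star]),
            NondimParams(-0.2, 0.1)))
        want = _sorted(eigenvalues_A(-0.2, 0.1))
        assert max(abs(a - b) for a, b in zip(got, want)) < 1e-6

    def test_rejects_non_steady_state(self):
        with pytest.raises(NotASteadyStateError):
            numerical_jacobian_eigs(np.array([1.2, 0.7, 0.3]),
                                    NondimParams(-0.3, 0.05))

    def test_grid_agreement_with_analytic_formulas(self):
        # analytic vs finite-difference eigenvalues over the existence
        # regions of the equal-amplitude branches
        for kappa in np.linspace(-1.9, 1.9, 8):
            for mu in np.linspace(-1.9, 1.9, 8):
                for label in ("I", "A", "L+", "L-"):
                    br = branch_value(label, mu, kappa)
                    if not br.exists or br.boundary:
                        continue
                    got = _sorted(numerical_jacobian_eigs(
                        np.array([br.R1_star, br.R2_star, br.phi_star]),
                        NondimParams(mu, kappa)))
                    want = _sorted(br.eigenvalues)
                    assert max(abs(a - b) for a, b in zip(got, want)) < 1e-6


class TestCatalogueProperties:
    def test_residuals_vanish_at_existing_branches(self):
        p_grid = np.linspace(-1.9, 1.9, 12)
        for kappa in p_grid:
            for mu in p_grid:
                for label in MAIN_BRANCHES:
                    br = branch_value(label, mu, kappa,
                                      attach_eigenvalues=False)
                    if not br.exists or br.boundary:
                        continue
                    res = np.linalg.norm(ahkb_rhs_nondim(
                        [br.R1_star, br.R2_star, br.phi_star],
                        NondimParams(mu, kappa), _guarded=False))
                    assert res < 1e-12, (label, mu, kappa, res)

    def test_unequal_amplitude_branches_unstable_where_they_exist(self):
        for kappa in np.linspace(-1.9, 1.9, 10):
            for mu in np.linspace(-1.9, 1.9, 10):
                for label in ("N0+", "N0-", "Npi+", "Npi-"):
                    br = branch_value(label, mu, kappa)
                    if br.exists and not br.boundary and br.eigenvalues:
                        assert max(complex(e).real
                                   for e in br.eigenvalues) > 0

    def test_degenerate_family_reports_degenerate(self):
        for label in ("Z0", "Zpi", "Zphi"):
            assert branch_value(label, 0.0, 0.3).stable == "degenerate"


class TestBifurcationGeometry:
    def test_lines_contain_printed_points(self):
        by = {ln.label: ln for ln in bifurcation_lines()}
        assert by["BP_AA"].contains(mu=1.0, kappa=-1.0)
        assert by["BP_II"].contains(mu=1.0, kappa=-1.0)
        assert by["BP_N"].contains(mu=1.0, kappa=-1.0)
        assert not by["HB_A"].contains(mu=0.0, kappa=0.0)
        assert by["HB_A"].contains(mu=-0.5, kappa=1.3)
        assert by["BP_AL"].contains(mu=-0.4, kappa=0.1)

    def test_dimensional_hopf_lines(self):
        assert hb_i_dimensional(0.0, 5.0) == 0.0
        assert hb_a_dimensional(1.0, -0.5) == 0.0

    def test_triple_intersection_point(self):
        kappa, mu = triple_intersection()
        assert (kappa, mu) == (-1.0, 1.0)
        # reciprocal parameterisation lands on (nu, sigma) = (1, -1)
        assert (1 / mu, 1 / kappa) == (1.0, -1.0)
        for ln in bifurcation_lines():
            if ln.label in ("BP_N", "BP_II", "BP_AA"):
                assert ln.residual(mu, kappa) == 0.0

    def test_phase_lag_lines(self):
        l90 = phase_lag_line(math.pi / 2)
        assert l90.residual(mu=1.0, kappa=-0.5) == pytest.approx(0.0, abs=1e-15)
        l120 = phase_lag_line(2 * math.pi / 3)  # mu = -3 kappa
        assert l120.residual(mu=3.0, kappa=-1.0) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="branch I"):
            phase_lag_line(0.0)
        with pytest.raises(ValueError):
            phase_lag_line(math.pi)

    def test_eigenvalue_crossing_sits_on_bp_al(self):
        # zero of branch A's third eigenvalue in mu, at fixed kappa,
        # located by bisection, lies on mu + 4 kappa = 0
        kappa = 0.05
        lo, hi = -0.4, 0.1
        f = lambda mu: eigenvalues_A(mu, kappa)[2]
        assert f(lo) * f(hi) < 0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert 0.5 * (lo + hi) == pytest.approx(-4 * kappa, abs=1e-8)


class TestStabilityChart:
    def test_bistable_cell(self):
        df = stability_chart((0.1, 0.1), (-0.2, -0.2), grid_n=2)
        stable = set(df.iloc[0]["stable"].split(";"))
        assert {"I", "A"} <= stable

    def test_lagged_cell(self):
        df = stability_chart((-0.5, -0.5), (1.0, 1.0), grid_n=2)
        stable = set(df.iloc[0]["stable"].split(";"))
        assert {"L+", "L-"} <= stable and "I" not in stable

    def test_bistability_and_lag_need_opposite_parameter_signs(self):
        df = stability_chart((-1.5, 1.5), (-1.5, 1.5), grid_n=21)
        for _, row in df.iterrows():
            stable = [s for s in row["stable"].split(";") if s]
            if len(stable) > 1 or any(s.startswith("L") for s in stable):
                assert row["mu"] * row["kappa"] < 0

    def test_rejects_degenerate_grid(self):
        with pytest.raises(ValueError):
            stability_chart(grid_n=1)


class TestDimensionalBistability:
    def test_wedge_membership(self):
        p = HKBParams(1.0, 1, 1, -0.1, 0.5, 0, 2.0)
        # a<0; b<13/8; a*13 + 4*0.5 = 0.7 > 0
        assert bistability_region_dimensional(p)

    def test_positive_linear_coupling_excluded(self):
        assert not bistability_region_dimensional(
            HKBParams(1.0, 1, 1, 0.1, 0.5, 0, 2.0))

    def test_boundary_is_bp_al_image(self):
        # a (alpha+3 beta w^2) + 4 gamma b = 0 maps to mu + 4 kappa = 0
        p = HKBParams(1.0, 1, 1, -0.5, 13.0 / 8.0 * 0.99, 0, 2.0)
        a_boundary = -4 * p.gamma * p.b / 13.0
        v = bistability_region_dimensional(
            HKBParams(1.0, 1, 1, a_boundary, p.b, 0, 2.0), tol=1e-9)
        assert v.on_boundary and not v.bistable

    def test_assumption_violation_redirects(self):
        with pytest.raises(ValueError, match="sign-generalised"):
            bistability_region_dimensional(
                HKBParams(-1.0, 1, 1, -0.1, 0.5, 0, 2.0))


def test_catalogue_covers_all_labels():
    for label in ALL_BRANCHES:
        br = branch_value(label, 0.5, -0.5)
        assert br.label == label
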