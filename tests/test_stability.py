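import numpy as np
import pytest

from laborbasin.ode_model import DimensionlessParams, PhaseState, rhs_dimensionless
from laborbasin.stability import (
    SingularIntermediateError,
    ComplexEigenvaluesError,
    classify,
    detect_bifurcations,
    characteristic_coefficients,
    eigenvalues_at,
    equilibria,
    intermediate_equilibrium,
    jacobian,
)


def params(b, i, k=1.0):
    return DimensionlessParams(b=b, i=i, k=k)


class TestEquilibria:
    def test_interior_point_closed_form(self):
        reports = {r.label: r for r in equilibria(params(0.5, 0.5))}
        assert set(reports) == {"trivial", "quiescent", "laboring", "intermediate"}
        assert reports["intermediate"].location == pytest.approx((1 / 3, 1 / 3))

    def test_all_locations_are_fixed_points(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            b, i = rng.uniform(0.05, 0.95, size=2)
            k = rng.uniform(i + 0.02, 1.0) if i < 0.97 else 1.0
            for rep in equilibria(params(b, i, k)):
                res = rhs_dimensionless(PhaseState(*rep.location), params(b, i, k))
                assert max(abs(res[0]), abs(res[1])) < 1e-10

    def test_intermediate_collides_with_quiescent_when_i_equals_k(self):
        assert intermediate_equilibrium(params(0.4, 0.7, 0.7)) == pytest.approx((1.0, 0.0))

    def test_intermediate_collides_with_laboring_when_b_is_one(self):
        assert intermediate_equilibrium(params(1.0, 0.5)) == pytest.approx((0.0, 1.0))

    def test_singular_when_k_equals_bi(self):
        with pytest.raises(SingularIntermediateError):
            intermediate_equilibrium(DimensionlessParams(b=0.8, i=0.5, k=0.4))

    def test_outside_square_reported_absent(self):
        # i > k pushes the interior point out of the square; it is omitted
        reports = equilibria(DimensionlessParams(b=0.5, i=0.9, k=0.6))
        assert all(r.label != "intermediate" for r in reports)


class TestJacobian:
    def test_origin_is_diagonal(self):
        J = jacobian(PhaseState(0.0, 0.0), params(0.5, 0.3))
        assert J == pytest.approx(np.array([[0.5, 0.0], [0.0, 0.3]]))

    def test_quiescent_corner(self):
        J = jacobian(PhaseState(1.0, 0.0), params(0.5, 0.3, 0.9))
        assert J == pytest.approx(np.array([[-0.5, -1.0], [0.0, 0.3 - 0.9]]))

    def test_laboring_corner(self):
        J = jacobian(PhaseState(0.0, 1.0), params(0.5, 0.3, 0.9))
        assert J == pytest.approx(np.array([[0.5 - 1.0, 0.0], [-1.0, -0.3]]))


class TestEigenvalues:
    @pytest.mark.parametrize(
        "point, closed_form",
        [
            ((0.0, 0.0), lambda b, i, k: {b, i}),
            ((1.0, 0.0), lambda b, i, k: {i - k, -b}),
            ((0.0, 1.0), lambda b, i, k: {b - 1, -i}),
        ],
    )
    def test_corner_closed_forms(self, point, closed_form):
        rng = np.random.default_rng(1)
        for _ in range(50):
            b, i = rng.uniform(0.05, 0.95, size=2)
            k = rng.uniform(0.05, 1.0)
            (l1, l2), beta, gamma, is_complex = eigenvalues_at(
                PhaseState(*point), params(b, i, k)
            )
            assert not is_complex
            assert l1 >= l2
            expected = sorted(closed_form(b, i, k), reverse=True)
            assert [l1, l2] == pytest.approx(expected, abs=1e-12)

    def test_quadratic_matches_direct_eigendecomposition(self):
        """The printed (beta, gamma) roots must agree with numpy's
        eigendecomposition of the Jacobian at every equilibrium."""
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(250):
            b, i = rng.uniform(0.02, 0.98, size=2)
            k = rng.uniform(0.02, 1.0)
            p = params(b, i, k)
            try:
                reports = equilibria(p)
            except SingularIntermediateError:
                continue
            for rep in reports:
                direct = np.linalg.eigvals(jacobian(PhaseState(*rep.location), p))
                mine = np.array(rep.eigenvalues)
                assert np.allclose(
                    np.sort_complex(mine), np.sort_complex(direct), atol=1e-10
                )
                checked += 1
        assert checked >= 200

    def test_beta_gamma_are_trace_and_determinant(self):
        p = params(0.37, 0.61, 0.88)
        for rep in equilibria(p):
            J = jacobian(PhaseState(*rep.location), p)
            beta, gamma = characteristic_coefficients(PhaseState(*rep.location), p)
            assert beta == pytest.approx(-np.trace(J), abs=1e-12)
            assert gamma == pytest.approx(np.linalg.det(J), abs=1e-12)

    def test_non_equilibrium_point_rejected(self):
        with pytest.raises(Exception):
            eigenvalues_at(PhaseState(0.5, 0.5), params(0.5, 0.3))


class TestClassification:
    def test_trivial_is_source(self):
        reports = {r.label: r for r in equilibria(params(0.5, 0.3))}
        assert reports["trivial"].stability == "source"

    def test_quiescent_is_sink_when_i_below_k(self):
        reports = {r.label: r for r in equilibria(params(0.5, 0.3))}
        assert reports["quiescent"].stability == "sink"

    def test_intermediate_is_saddle(self):
        reports = {r.label: r for r in equilibria(params(0.5, 0.3))}
        assert reports["intermediate"].stability == "saddle"

    def test_zero_eigenvalue_is_degenerate(self):
        assert classify((0.0, -0.5)) == "degenerate"

    def test_complex_pair_raises(self):
        with pytest.raises(ComplexEigenvaluesError):
            classify((complex(0, 1), complex(0, -1)), complex_pair=True)


class TestBifurcations:
    @pytest.mark.parametrize(
        "b, i, k, flag",
        [
            (0.5, 1.0, 1.0, "pro_labor"),       # i = 1: quiescence destabilized
            (0.5, 0.8, 0.7, "pro_labor"),       # i >= k
            (1.0, 0.5, 1.0, "pro_pregnancy"),   # b = 1: labor destabilized
            (0.5, 0.0, 1.0, "pro_pregnancy"),   # i = 0
            (0.0, 0.0, 1.0, "trivial_collision"),
            (0.8, 0.5, 0.4, "singular_intermediate"),  # k = b*i
        ],
    )
    def test_flags(self, b, i, k, flag):
        report = detect_bifurcations(DimensionlessParams(b=b, i=i, k=k))
        assert getattr(report, flag) is True

    def test_interior_parameters_raise_no_flags(self):
        report = detect_bifurcations(params(0.5, 0.3, 0.9))
        assert not any(
            [report.pro_labor, report.pro_pregnancy,
             report.trivial_collision, report.singular_intermediate]
        )

    def test_quiescent_eigenvalue_vanishes_at_pro_labor_threshold(self):
        # at i = k the quiescent corner has one zero and one negative eigenvalue
        reports = {r.label: r for r in equilibria(params(0.5, 1.0, 1.0))}
        lams = sorted(np.real(reports["quiescent"].eigenvalues))
        assert lams[1] == pytest.approx(0.0, abs=1e-12)
        assert lams[0] == pytest.approx(-0.5)
        assert reports["quiescent"].stability == "degenerate"
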