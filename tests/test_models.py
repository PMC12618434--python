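"""Symbolic system handling: Jacobians, characteristic and Routh polynomials,
steady-state solving and stability verdicts."""

import itertools

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from stabscape import models
from stabscape.models import (
    BOUNDARY,
    STABLE,
    UNSTABLE,
    CharPoly,
    ParametricODESystem,
    char_poly,
    finite_difference_jacobian,
    is_stable,
    jacobian,
    routh_polynomials,
    steady_states,
)


def _charpoly_bruteforce(M, lam):
    """Independent oracle: det(lam*I - M) by permutation expansion."""
    n = M.rows
    A = lam * sp.eye(n) - M
    total = sp.Integer(0)
    from sympy.combinatorics import Permutation

    for perm in itertools.permutations(range(n)):
        sign = Permutation(perm).signature()
        term = sp.Integer(1)
        for i, j in enumerate(perm):
            term *= A[i, j]
        total += sign * term
    return sp.expand(total)


class TestPredatorPreyWorkedExample:
    """The Holling Type II predator-prey system with a strong Allee effect at
    (alpha, beta, gamma, m, K) = (2, 3/2, 1, 1/2, 1)."""

    @pytest.fixture(scope="class")
    def system(self, registry):
        return registry["predator_prey_fixed"]

    def coexistence_jacobian(self, system, A, x, y):
        J = jacobian(system)
        subs = {sp.Symbol("A"): A, system.variables[0]: x, system.variables[1]: y}
        return J.subs(subs)

    def test_trace_and_determinant_at_A_nine_quarters(self, system):
        J = self.coexistence_jacobian(system, sp.Rational(9, 4), 2, sp.Rational(2, 9))
        assert sp.simplify(J.trace()) == sp.Rational(-7, 12)
        assert sp.simplify(J.det()) == sp.Rational(1, 72)
        cp = char_poly(J)
        assert cp.coeffs == (sp.Rational(1, 72), sp.Rational(7, 12), sp.Integer(1))
        assert routh_polynomials(cp) == [sp.Rational(7, 12), sp.Rational(1, 72)]
        assert is_stable(J) == STABLE

    def test_unstable_beyond_the_stability_boundary(self, system):
        J = self.coexistence_jacobian(system, sp.Integer(3), 2, sp.Rational(2, 3))
        assert sp.simplify(J.trace()) == sp.Rational(1, 4)
        assert is_stable(J) == UNSTABLE

    def test_trace_vanishes_on_the_stability_boundary(self, system):
        J = self.coexistence_jacobian(
            system, sp.Rational(30, 11), 2, sp.Rational(8, 15)
        )
        assert sp.simplify(J.trace()) == 0
        assert is_stable(J) == BOUNDARY

    def test_four_steady_states_with_coexistence(self, system):
        sols = steady_states(system, {"A": sp.Rational(9, 4)})
        reals = sorted(s.real_coords for s in sols.real())
        assert len(reals) == 4
        assert reals[0] == pytest.approx((0.0, 0.0), abs=1e-10)
        coords = {tuple(np.round(r, 6)) for r in reals}
        assert (1.0, 0.0) in coords  # (K, 0)
        assert (2.25, 0.0) in coords  # (A, 0)
        assert (2.0, pytest.approx(2 / 9, abs=1e-9)) in [
            (r[0], r[1]) for r in reals
        ]
        assert all(s.residual < 1e-8 for s in sols.states)
        coex = [s for s in sols.real_positive()]
        assert len(coex) == 1 and coex[0].verdict == STABLE


class TestJacobian:
    def test_one_variable_linear_decay(self):
        sys = ParametricODESystem.from_strings(["x"], ["a"], ["-x + 0*a"])
        assert jacobian(sys) == sp.Matrix([[-1]])

    def test_matches_finite_differences_on_random_cubic(self):
        rng = np.random.default_rng(42)
        coeffs = rng.integers(-3, 4, size=(2, 10))
        x, y = sp.symbols("x y")
        monoms = [1, x, y, x**2, x * y, y**2, x**3, x**2 * y, x * y**2, y**3]
        a = sp.Symbol("a")
        rates = [
            str(sum(int(c) * m for c, m in zip(row, monoms)) + a * x).replace("**", "^")
            for row in coeffs
        ]
        sys = ParametricODESystem.from_strings(["x", "y"], ["a"], rates)
        J = jacobian(sys)
        f = sp.lambdify((x, y, a), J, "numpy")
        for _ in range(20):
            pt = rng.uniform(-2, 2, size=3)
            exact = np.array(f(*pt), dtype=float)
            approx = finite_difference_jacobian(sys, {"x": pt[0], "y": pt[1], "a": pt[2]})
            scale = 1 + np.abs(exact)
            assert np.all(np.abs(exact - approx) / scale < 1e-6)


class TestCharPoly:
    def test_negative_identity(self):
        cp = char_poly(-sp.eye(2))
        assert cp.coeffs == (sp.Integer(1), sp.Integer(2), sp.Integer(1))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            char_poly(sp.Matrix([[1, 2, 3], [4, 5, 6]]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_permutation_expansion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = sp.Matrix(rng.integers(-5, 6, size=(3, 3)).tolist())
        lam = sp.Symbol("lam")
        cp = char_poly(M)
        assert sp.expand(cp.as_expr(lam) - _charpoly_bruteforce(M, lam)) == 0

    def test_symbolic_identities_on_fixtures(self, registry):
        for name in ("levins_culver", "coral_reduced"):
            sys = registry[name]
            J = jacobian(sys)
            cp = char_poly(J)
            n = sys.n
            assert sp.simplify(cp.coeffs[n - 1] + J.trace()) == 0
            assert sp.simplify(cp.coeffs[0] - (-1) ** n * J.det()) == 0


class TestRouthPolynomials:
    def test_small_dimensions(self):
        c0, c1, c2 = sp.symbols("c0 c1 c2")
        assert routh_polynomials(CharPoly((c0, sp.Integer(1)))) == [c0]
        assert routh_polynomials(CharPoly((c0, c1, sp.Integer(1)))) == [c1, c0]
        r3 = routh_polynomials(CharPoly((c0, c1, c2, sp.Integer(1))))
        assert [sp.expand(r) for r in r3] == [c2, sp.expand(c2 * c1 - c0), c0]

    def test_one_dimensional_decay_is_stable(self):
        sys = ParametricODESystem.from_strings(["x"], ["a"], ["-x + 0*a"])
        cp = char_poly(jacobian(sys))
        assert routh_polynomials(cp) == [sp.Integer(1)]

    def test_non_monic_rejected(self):
        with pytest.raises(ValueError):
            CharPoly((sp.Integer(1), sp.Integer(2)))


class TestIsStable:
    def test_negative_identity_is_stable(self):
        assert is_stable(np.diag([-1.0, -1.0])) == STABLE

    @given(
        st.lists(
            st.integers(min_value=-9, max_value=9), min_size=9, max_size=9
        )
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_routh_verdict_matches_eigenvalues(self, entries):
        J = np.array(entries, dtype=float).reshape(3, 3)
        spectral = float(np.max(np.real(np.linalg.eigvals(J))))
        if abs(spectral) < 1e-6:
            return  # undecidable at tolerance; boundary case
        verdict = is_stable(J)
        assert verdict == (STABLE if spectral < 0 else UNSTABLE)


class TestSteadyStates:
    def test_levins_culver_coexistence_closed_form(self, lc_system):
        a = {
            "beta_y": sp.Rational(3, 2),
            "beta_z": sp.Integer(6),
            "gamma_y": sp.Rational(1, 2),
            "gamma_z": sp.Rational(1, 3),
        }
        sols = steady_states(lc_system, a)
        y_expected = 1 - sp.Rational(1, 2) / sp.Rational(3, 2)
        z_expected = sp.Rational(1, 2) / sp.Rational(3, 2) - (
            sp.Rational(1, 3) + sp.Rational(3, 2) - sp.Rational(1, 2)
        ) / sp.Integer(6)
        target = (float(y_expected), float(z_expected))
        found = [s.real_coords for s in sols.real_positive()]
        assert any(np.allclose(rc, target, atol=1e-9) for rc in found)

    @pytest.mark.parametrize("name", ["levins_culver", "coral_reduced"])
    def test_origin_is_always_a_steady_state(self, registry, name):
        sys = registry[name]
        a = {p.name: sp.Rational(3, 2) for p in sys.parameters}
        sols = steady_states(sys, a)
        origins = [
            s for s in sols.real() if np.allclose(s.real_coords, 0.0, atol=1e-10)
        ]
        assert len(origins) == 1

    def test_residuals_below_tolerance(self, lc_system):
        a = {p.name: sp.Rational(5, 4) for p in lc_system.parameters}
        sols = steady_states(lc_system, a)
        assert sols.states and all(s.residual < 1e-8 for s in sols.states)


class TestSystemConstruction:
    def test_fixed_substitution_removes_parameter(self, registry):
        pp = registry["predator_prey_fixed"]
        assert [p.name for p in pp.parameters] == ["A"]
        assert len(pp.fixed) == 5

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ParametricODESystem.from_strings(["x"], ["a"], ["x / (a - a)"])

    def test_needs_free_parameter(self):
        with pytest.raises(ValueError):
            ParametricODESystem.from_strings(["x"], ["a"], ["a*x"], fixed={"a": 1})
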