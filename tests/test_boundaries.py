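"""Equilibrium-ideal decomposition and the three boundary types
(singular, Routh-Hurwitz, coordinate) assembled into arrangements."""

import numpy as np
import pytest
import sympy as sp

from stabscape.boundaries import (
    EliminationTimeout,
    HypersurfaceArrangement,
    canonical_factor,
    coordinate_boundary,
    decompose_equilibrium_ideal,
    eliminate,
    eliminate_with_timeout,
    routh_hurwitz_boundary,
    singular_boundary,
    total_boundary,
)
from stabscape.models import ParametricODESystem, steady_states


def _factor_set(factors, symbols):
    return {sp.expand(canonical_factor(f, symbols)) for f in factors}


def _sylvester_resultant(f, g, x):
    """Independent oracle: resultant via an explicitly built Sylvester matrix."""
    fp, gp = sp.Poly(f, x), sp.Poly(g, x)
    m, n = fp.degree(), gp.degree()
    fc, gc = fp.all_coeffs(), gp.all_coeffs()
    size = m + n
    M = sp.zeros(size, size)
    for i in range(n):
        for j, c in enumerate(fc):
            M[i, i + j] = c
    for i in range(m):
        for j, c in enumerate(gc):
            M[n + i, i + j] = c
    return sp.expand(M.det())


class TestSingularBoundary:
    def test_quadratic_discriminant(self, registry):
        sys = registry["quadratic_discriminant"]
        comp = decompose_equilibrium_ideal(sys)[0]
        factors = singular_boundary(comp, sys)
        a1, a2, a3 = sys.parameters
        assert _factor_set(factors, sys.parameters) == {
            sp.expand(canonical_factor(a2**2 - 4 * a1 * a3, sys.parameters))
        }

    def test_double_root_toy(self):
        sys = ParametricODESystem.from_strings(["x"], ["a1"], ["x^2 - a1"])
        comp = decompose_equilibrium_ideal(sys)[0]
        assert _factor_set(singular_boundary(comp, sys), sys.parameters) == {
            sys.parameters[0]
        }

    def test_depressed_cubic_matches_sylvester_oracle(self):
        sys = ParametricODESystem.from_strings(
            ["x"], ["a1", "a2"], ["x^3 + a1*x + a2"]
        )
        comp = decompose_equilibrium_ideal(sys)[0]
        factors = singular_boundary(comp, sys)
        x = sys.variables[0]
        f = x**3 + sys.parameters[0] * x + sys.parameters[1]
        oracle = _sylvester_resultant(f, sp.diff(f, x), x)
        expected = _factor_set([oracle], sys.parameters)
        assert _factor_set(factors, sys.parameters) == expected
        assert sp.expand(
            canonical_factor(4 * sys.parameters[0] ** 3 + 27 * sys.parameters[1] ** 2,
                             sys.parameters)
        ) in expected


class TestDecomposition:
    def test_levins_culver_four_printed_components(self, lc_system, lc_components):
        assert len(lc_components) == 4
        y, z = lc_system.variables
        by, bz, gy, gz = [sp.Symbol(n) for n in ("beta_y", "beta_z", "gamma_y", "gamma_z")]
        expected = [
            [y, z],
            [by * (1 - y) - gy, z],
            [y, bz * (1 - z) - gz],
            [by * (1 - y) - gy, bz * (1 - y - z) - by * y - gz],
        ]
        symbols = list(lc_system.variables) + list(lc_system.parameters)

        def ideal_key(gens):
            G = sp.groebner([sp.expand(g) for g in gens], *symbols, order="grevlex")
            return tuple(sorted(str(sp.expand(canonical_factor(e, symbols))) for e in G.exprs))

        got = {ideal_key(c.generators) for c in lc_components}
        want = {ideal_key(gens) for gens in expected}
        assert got == want

    def test_levins_culver_labels(self, lc_components):
        assert sorted(c.label for c in lc_components) == ["E_0", "E_co", "E_y", "E_z"]

    def test_coral_five_equilibrium_types(self, coral_components):
        labels = sorted(c.label for c in coral_components)
        assert labels == ["E_0", "E_co", "E_x", "E_xy", "E_xz"]

    def test_logistic_splits_into_two_components(self):
        sys = ParametricODESystem.from_strings(["x"], ["r"], ["r*x*(1 - x)"])
        comps = decompose_equilibrium_ideal(sys)
        gens = sorted(str(sp.expand(c.generators[0])) for c in comps)
        assert len(comps) == 2
        assert gens == ["1 - x", "x"] or gens == ["x", "x - 1"]

    def test_union_of_components_equals_direct_solutions(self, lc_system, lc_components):
        """At random parameter points the component varieties reproduce the
        full solution set of the system."""
        from stabscape.landscape import ComponentSolver

        solvers = [ComponentSolver(c, lc_system) for c in lc_components]
        rng = np.random.default_rng(3)
        for _ in range(10):
            vals = [sp.Rational(int(v), 16) for v in rng.integers(8, 64, size=4)]
            a = dict(zip([p.name for p in lc_system.parameters], vals))
            direct = steady_states(lc_system, a)
            direct_pts = sorted(
                tuple(np.round(s.real_coords, 8)) for s in direct.real()
            )
            union = []
            for solver in solvers:
                for coords in solver.solve([float(v) for v in vals]):
                    if all(abs(c.imag) < 1e-8 for c in coords):
                        union.append(tuple(np.round([c.real for c in coords], 8)))
            assert sorted(set(union)) == sorted(set(direct_pts))


class TestCoordinateBoundary:
    def test_levins_culver_coexistence_z_boundary_is_g6(self, lc_system, lc_components):
        comp = next(c for c in lc_components if c.label == "E_co")
        result = coordinate_boundary(comp, "z", lc_system)
        by, bz, gy, gz = [sp.Symbol(n) for n in ("beta_y", "beta_z", "gamma_y", "gamma_z")]
        g6 = by**2 - by * gy - bz * gy + by * gz
        assert _factor_set(result.factors, lc_system.parameters) == _factor_set(
            [g6], lc_system.parameters
        )

    def test_identically_zero_coordinate_is_skipped(self, lc_system, lc_components):
        comp = next(c for c in lc_components if c.label == "E_y")  # z == 0 there
        result = coordinate_boundary(comp, "z", lc_system)
        assert result.kind == "zero" and not result.factors

    def test_shifted_root_toy(self):
        sys = ParametricODESystem.from_strings(["x"], ["a1"], ["x - a1"])
        comp = decompose_equilibrium_ideal(sys)[0]
        result = coordinate_boundary(comp, "x", sys)
        assert _factor_set(result.factors, sys.parameters) == {sys.parameters[0]}


class TestRouthHurwitzBoundary:
    def test_predator_prey_trace_boundary_at_A_30_over_11(self, registry):
        sys = registry["predator_prey_fixed"]
        comps = decompose_equilibrium_ideal(sys)
        coex = next(c for c in comps if c.label == "E_co")
        factors = routh_hurwitz_boundary(coex, sys)
        A = sys.parameters[0]
        roots = set()
        for f in factors:
            roots |= {r for r in sp.roots(sp.Poly(f, A)) if r.is_real}
        assert sp.Rational(30, 11) in roots

    def test_always_stable_linear_system_has_empty_boundary(self):
        sys = ParametricODESystem.from_strings(["x"], ["a1"], ["a1 - x"])
        comp = decompose_equilibrium_ideal(sys)[0]
        assert routh_hurwitz_boundary(comp, sys) == []


class TestTotalBoundary:
    def test_levins_culver_printed_factors_exactly(self, lc_system, lc_arrangement):
        by, bz, gy, gz = [sp.Symbol(n) for n in ("beta_y", "beta_z", "gamma_y", "gamma_z")]
        printed = [
            by - gy,
            bz - gz,
            by - bz - gy + gz,
            by + bz - gy - gz,
            bz * gy - by * gz,
            by**2 - by * gy - bz * gy + by * gz,
            2 * by**2 - 2 * by * gy - bz * gy + by * gz,
        ]
        params = lc_system.parameters
        got = _factor_set(lc_arrangement.boundary_factors(), params)
        assert got == _factor_set(printed, params)

    def test_levins_culver_eleven_hypersurfaces(self, lc_arrangement):
        assert lc_arrangement.m == 11
        assert sum(lc_arrangement.is_coordinate) == 4

    def test_user_arrangement_passthrough(self, registry):
        arr = registry["two_ellipses"]
        renorm = HypersurfaceArrangement.from_polynomials(
            arr.parameters, [7 * p for p in arr.polynomials]
        )
        assert _factor_set(renorm.polynomials, arr.parameters) == _factor_set(
            arr.polynomials, arr.parameters
        )
        assert renorm.degrees == [2, 2]

    def test_elimination_methods_agree_on_levins_culver(self, lc_system, lc_components):
        symbols = lc_system.parameters
        for comp in lc_components:
            auto = routh_hurwitz_boundary(comp, lc_system, method="auto")
            grb = routh_hurwitz_boundary(comp, lc_system, method="groebner")
            assert _factor_set(auto, symbols) == _factor_set(grb, symbols)

    def test_provenance_tags_present(self, lc_arrangement):
        tagged = [
            tags for tags in lc_arrangement.provenance.values() if tags
        ]
        assert tagged and all(
            isinstance(t, tuple) and len(t) == 2 for tags in tagged for t in tags
        )


class TestBoundarySoundness:
    """Sampled points on each boundary hypersurface exhibit the defining
    degeneracy of the boundary type that produced them."""

    def test_coordinate_boundary_points_have_a_zero_coordinate(
        self, lc_system, lc_components
    ):
        comp = next(c for c in lc_components if c.label == "E_co")
        g6 = coordinate_boundary(comp, "z", lc_system).factors[0]
        by, bz, gy, gz = [sp.Symbol(n) for n in ("beta_y", "beta_z", "gamma_y", "gamma_z")]
        rng = np.random.default_rng(7)
        from stabscape.landscape import ComponentSolver

        solver = ComponentSolver(comp, lc_system)
        checked = 0
        for _ in range(60):
            vals = {
                by: sp.Rational(int(rng.integers(12, 40)), 16),
                gy: sp.Rational(int(rng.integers(4, 20)), 16),
                gz: sp.Rational(int(rng.integers(4, 20)), 16),
            }
            sols = sp.solve(g6.subs(vals), bz)
            for bz_val in sols:
                if not bz_val.is_real or bz_val <= 0:
                    continue
                point = {**vals, bz: bz_val}
                a = [float(point[p]) for p in lc_system.parameters]
                for coords in solver.solve(a):
                    if all(abs(c.imag) < 1e-8 for c in coords):
                        z_val = coords[1].real
                        if abs(z_val) < 1e-6:
                            checked += 1
            if checked >= 20:
                break
        assert checked >= 20


class TestEliminationInfrastructure:
    def test_timeout_raises_with_context(self, registry):
        coral = registry["coral_reduced"]
        comps = decompose_equilibrium_ideal(coral)
        coex = next(c for c in comps if c.label == "E_co")
        with pytest.raises(EliminationTimeout):
            # full 4-parameter coexistence elimination via Groebner is far
            # beyond a millisecond budget
            eliminate_with_timeout(
                list(coex.generators) + [sp.expand(coex.generators[-1] ** 2 + 1)],
                coral.variables,
                coral.parameters,
                method="groebner",
                timeout=0.01,
                context="test",
            )

    def test_codimension_two_contributes_no_hypersurface(self):
        a1, a2, x = sp.symbols("a1 a2 x")
        result = eliminate([x - a1, x - a2, x], [x], [a1, a2])
        assert result.kind in ("codim_ge_2", "hypersurface")
        # the elimination ideal is <a1, a2> with gcd 1: no hypersurface part
        assert result.kind == "codim_ge_2" or result.factors == []
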