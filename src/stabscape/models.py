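"""Parametric ODE systems: Jacobians, characteristic and Routh polynomials,
steady-state solving, and local stability classification.

The central object is :class:`ParametricODESystem`, an autonomous system
``dx/dt = f(x; a)`` with rational rate laws over exact rational coefficients,
``x`` the nonnegative state variables and ``a`` the positive parameters.
Local asymptotic stability of a steady state is decided through the
Routh-Hurwitz criterion: with the characteristic polynomial of the Jacobian
written monically as ``lambda^n + c_{n-1} lambda^{n-1} + ... + c_0``, the
state is stable iff the leading principal minors of the Hurwitz matrix and
``c_0`` are all positive.  Verdicts are cross-checked against the eigenvalue
real parts so that a convention slip in the Hurwitz construction cannot pass
silently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

from .expressions import ExpressionError, parse_expression

__all__ = [
    "ParametricODESystem",
    "CharPoly",
    "SteadyState",
    "SteadyStateSolutionSet",
    "jacobian",
    "char_poly",
    "routh_polynomials",
    "hurwitz_matrix",
    "is_stable",
    "steady_states",
    "STABLE",
    "UNSTABLE",
    "BOUNDARY",
]

STABLE = "stable"
UNSTABLE = "unstable"
BOUNDARY = "boundary"

#: Default tolerance on Routh-polynomial values; points within it are
#: reported "boundary", never silently classified.
STABILITY_TOL = 1e-9
#: Strict positivity threshold on steady-state coordinates.
POSITIVITY_TOL = 1e-9
#: Residual bound every returned steady state must satisfy.
RESIDUAL_TOL = 1e-8


def _to_rational(value) -> sp.Rational:
    """Convert ints, strings like ``"3/2"``, Fractions and Rationals exactly."""
    if isinstance(value, sp.Rational):
        return value
    if isinstance(value, (int, Fraction)):
        return sp.Rational(value)
    if isinstance(value, str):
        return sp.Rational(Fraction(value))
    if isinstance(value, float):
        # floats are binary rationals; conversion is exact
        return sp.Rational(Fraction(value))
    raise TypeError(f"cannot interpret {value!r} as an exact rational")


@dataclass(frozen=True)
class ParametricODESystem:
    """An autonomous ODE system ``dx/dt = f(x; a)`` with rational rates.

    Parameters named in ``fixed`` are substituted at construction and removed
    from the free parameter list, mirroring the common workflow of pinning
    rate constants before a landscape computation.
    """

    variables: tuple[sp.Symbol, ...]
    parameters: tuple[sp.Symbol, ...]
    rates: tuple[sp.Expr, ...]
    fixed: tuple[tuple[sp.Symbol, sp.Rational], ...] = ()
    name: str = ""

    @classmethod
    def from_strings(
        cls,
        variables: Sequence[str],
        parameters: Sequence[str],
        rates: Sequence[str],
        fixed: Mapping[str, object] | None = None,
        name: str = "",
    ) -> "ParametricODESystem":
        var_syms = tuple(sp.Symbol(v) for v in variables)
        par_syms = tuple(sp.Symbol(p) for p in parameters)
        names = {s.name: s for s in var_syms + par_syms}
        if len(names) != len(var_syms) + len(par_syms):
            raise ValueError("variable/parameter names must be distinct")
        rate_exprs = [parse_expression(r, names) for r in rates]
        fixed = fixed or {}
        subs = {}
        for key, value in fixed.items():
            if key not in names or names[key] not in par_syms:
                raise ValueError(f"fixed substitution for unknown parameter {key!r}")
            subs[names[key]] = _to_rational(value)
        rate_exprs = [sp.cancel(r.subs(subs)) for r in rate_exprs]
        free_pars = tuple(p for p in par_syms if p not in subs)
        sys = cls(
            variables=var_syms,
            parameters=free_pars,
            rates=tuple(rate_exprs),
            fixed=tuple(sorted(subs.items(), key=lambda kv: kv[0].name)),
            name=name,
        )
        sys.validate()
        return sys

    def validate(self) -> None:
        if len(self.variables) < 1:
            raise ValueError("need at least one variable")
        if len(self.parameters) < 1:
            raise ValueError("need at least one free parameter after substitution")
        if len(self.rates) != len(self.variables):
            raise ValueError("need one rate per variable")
        allowed = set(self.variables) | set(self.parameters)
        for rate in self.rates:
            if rate.has(sp.zoo, sp.nan, sp.oo, -sp.oo):
                raise ValueError("rate denominator is identically zero")
            if not rate.free_symbols <= allowed:
                extra = rate.free_symbols - allowed
                raise ValueError(f"rate uses undeclared symbols {extra}")
            _, den = sp.fraction(sp.cancel(sp.together(rate)))
            if sp.simplify(den) == 0:
                raise ValueError("rate denominator is identically zero")

    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def k(self) -> int:
        return len(self.parameters)

    def fix(self, substitutions: Mapping[object, object], name: str = "") -> "ParametricODESystem":
        """Return a copy with additional parameters fixed to exact rationals."""
        subs = {}
        by_name = {p.name: p for p in self.parameters}
        for key, value in substitutions.items():
            sym = by_name.get(key.name if isinstance(key, sp.Symbol) else str(key))
            if sym is None:
                raise ValueError(f"unknown parameter {key!r}")
            subs[sym] = _to_rational(value)
        sys = ParametricODESystem(
            variables=self.variables,
            parameters=tuple(p for p in self.parameters if p not in subs),
            rates=tuple(sp.cancel(r.subs(subs)) for r in self.rates),
            fixed=tuple(
                sorted({**dict(self.fixed), **subs}.items(), key=lambda kv: kv[0].name)
            ),
            name=name or self.name,
        )
        sys.validate()
        return sys

    def polynomial_rates(self) -> tuple[tuple[sp.Expr, ...], tuple[sp.Expr, ...]]:
        """Clear denominators: return (numerators, denominators) per rate.

        Valid for steady-state analysis where the denominators do not vanish
        on the sets of interest; callers must check returned solutions against
        the denominator zero sets.
        """
        nums, dens = [], []
        for rate in self.rates:
            num, den = sp.fraction(sp.cancel(sp.together(rate)))
            nums.append(sp.expand(num))
            dens.append(den)
        return tuple(nums), tuple(dens)


@dataclass(frozen=True)
class CharPoly:
    """Monic characteristic polynomial ``det(lambda*I - J)``.

    ``coeffs`` stores ``(c_0, ..., c_n)`` in ascending degree with ``c_n = 1``;
    ``c_{n-1}`` equals the negated trace and ``c_0`` equals ``(-1)^n det``.
    """

    coeffs: tuple

    def __post_init__(self):
        if sp.simplify(self.coeffs[-1] - 1) != 0:
            raise ValueError("characteristic polynomial must be monic")

    @property
    def n(self) -> int:
        return len(self.coeffs) - 1

    def as_expr(self, lam: sp.Symbol) -> sp.Expr:
        return sum(c * lam**i for i, c in enumerate(self.coeffs))


def jacobian(sys: ParametricODESystem) -> sp.Matrix:
    """Symbolic Jacobian of the rates with respect to the variables."""
    return sp.Matrix(
        [[sp.cancel(sp.diff(rate, var)) for var in sys.variables] for rate in sys.rates]
    )


def char_poly(J, at_point: Mapping | None = None) -> CharPoly:
    """Monic characteristic polynomial of a (numeric or symbolic) square matrix.

    When entries are rational numbers, coefficients come out in exact rational
    arithmetic.  ``at_point`` optionally substitutes symbols before expansion.
    """
    M = sp.Matrix(J)
    if M.rows != M.cols:
        raise ValueError("characteristic polynomial needs a square matrix")
    if at_point:
        M = M.subs({k: _to_rational(v) if not isinstance(v, sp.Expr) else v
                    for k, v in at_point.items()})
    lam = sp.Dummy("lambda")
    poly = M.charpoly(lam)  # sympy returns det(lam*I - M), monic
    coeffs = list(reversed(poly.all_coeffs()))  # ascending: c_0 .. c_n
    coeffs = [sp.cancel(sp.together(c)) for c in coeffs]
    return CharPoly(coeffs=tuple(coeffs))


def hurwitz_matrix(cp: CharPoly) -> sp.Matrix:
    """Hurwitz matrix ``H[i][j] = c_{n - 2i + j}`` (1-based), out-of-range = 0."""
    n = cp.n
    def c(idx):
        return cp.coeffs[idx] if 0 <= idx <= n else sp.Integer(0)
    return sp.Matrix(n, n, lambda i, j: c(n - 2 * (i + 1) + (j + 1)))


def routh_polynomials(cp: CharPoly) -> list:
    """Routh polynomials: leading principal Hurwitz minors ``Delta_1..Delta_{n-1}``
    plus ``c_0``; positivity of all of them is the stability criterion.

    For n=1 this is ``[c_0]``; n=2: ``[c_1, c_0]``; n=3:
    ``[c_2, c_2*c_1 - c_3*c_0, c_0]``.
    """
    if sp.simplify(cp.coeffs[-1] - 1) != 0:
        raise ValueError("Routh polynomials require a monic characteristic polynomial")
    n = cp.n
    if n == 1:
        return [cp.coeffs[0]]
    H = hurwitz_matrix(cp)
    minors = [sp.expand(H[:i, :i].det()) for i in range(1, n)]
    return minors + [cp.coeffs[0]]


def _routh_values_numeric(J: np.ndarray) -> list[float]:
    # char poly of a real matrix has real coefficients; np.poly may carry a
    # tiny imaginary residue from the eigenvalue computation
    coeffs = np.real(np.poly(J))  # monic, descending
    cp = CharPoly(coeffs=tuple(sp.Float(float(c)) for c in reversed(coeffs)))
    return [float(r) for r in routh_polynomials(cp)]


def is_stable(J, tol: float = STABILITY_TOL) -> str:
    """Classify a numeric square matrix as stable / unstable / boundary.

    Stable iff every Routh polynomial exceeds ``tol``; boundary if some value
    lies within ``tol`` of zero and none is below ``-tol``.  The verdict is
    cross-checked against the eigenvalue real parts whenever both criteria are
    decisive; disagreement raises ``RuntimeError``.
    """
    if isinstance(J, sp.MatrixBase):
        M = sp.Matrix(J)
        if M.free_symbols:
            raise ValueError("is_stable needs a fully numeric matrix")
        values = [sp.nsimplify(r, rational=True) for r in routh_polynomials(char_poly(M))]
        numeric = [float(v) for v in values]
        arr = np.array(M.evalf(17), dtype=complex)
    else:
        arr = np.asarray(J, dtype=complex)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("is_stable needs a square matrix")
        numeric = _routh_values_numeric(arr)

    if all(v > tol for v in numeric):
        verdict = STABLE
    elif any(v < -tol for v in numeric):
        verdict = UNSTABLE
    else:
        verdict = BOUNDARY

    spectral = float(np.max(np.real(np.linalg.eigvals(arr))))
    if verdict == STABLE and spectral > 1e-7:
        raise RuntimeError("Routh criterion says stable but an eigenvalue real part is positive")
    if verdict == UNSTABLE and spectral < -1e-7:
        raise RuntimeError("Routh criterion says unstable but all eigenvalue real parts are negative")
    return verdict


@dataclass
class SteadyState:
    """One isolated solution of ``f(x; a*) = 0`` with its classification."""

    coords: tuple[complex, ...]
    multiplicity: int = 1
    residual: float = 0.0
    is_real: bool = False
    is_positive: bool = False
    verdict: str | None = None
    routh_values: tuple[float, ...] = ()

    @property
    def real_coords(self) -> tuple[float, ...]:
        return tuple(float(np.real(c)) for c in self.coords)


@dataclass
class SteadyStateSolutionSet:
    """All isolated complex steady states at one parameter point."""

    states: list[SteadyState] = field(default_factory=list)
    tol: float = RESIDUAL_TOL

    def real(self) -> list[SteadyState]:
        return [s for s in self.states if s.is_real]

    def real_positive(self) -> list[SteadyState]:
        return [s for s in self.states if s.is_real and s.is_positive]

    def stable(self) -> list[SteadyState]:
        return [s for s in self.real_positive() if s.verdict == STABLE]


class NonIsolatedSolutionsError(RuntimeError):
    """The equilibrium system has a positive-dimensional solution set."""


class DenominatorCollisionError(RuntimeError):
    """A relevant steady-state candidate lies on a rate-denominator zero set."""


def _substituted_polynomials(sys: ParametricODESystem, a_star: Mapping) -> tuple[list, list, dict]:
    by_name = {p.name: p for p in sys.parameters}
    subs = {}
    for key, value in a_star.items():
        sym = by_name.get(key.name if isinstance(key, sp.Symbol) else str(key))
        if sym is None:
            raise ValueError(f"unknown parameter {key!r}")
        subs[sym] = value if isinstance(value, sp.Expr) else _to_rational(value)
    missing = set(sys.parameters) - set(subs)
    if missing:
        raise ValueError(f"parameter values missing for {sorted(s.name for s in missing)}")
    nums, dens = sys.polynomial_rates()
    polys = [sp.expand(n.subs(subs)) for n in nums]
    den_exprs = [d.subs(subs) for d in dens]
    return polys, den_exprs, subs


def _solve_polynomial_system(polys, variables):
    """All isolated complex solutions via symbolic elimination (Groebner)."""
    ring_polys = [sp.Poly(p, *variables) for p in polys if sp.expand(p) != 0]
    if len(ring_polys) < len(variables):
        raise NonIsolatedSolutionsError("fewer independent equations than variables")
    basis = sp.groebner(ring_polys, *variables, order="grevlex")
    if basis.exprs == [sp.Integer(1)]:
        return []
    if not basis.is_zero_dimensional:
        raise NonIsolatedSolutionsError("equilibrium system is not zero-dimensional")
    sols = sp.solve_poly_system(ring_polys, *variables)
    out = []
    for sol in sols:
        out.append(tuple(complex(sp.N(c, 30)) for c in sol))
    return out


def steady_states(
    sys: ParametricODESystem,
    a_star: Mapping,
    tol: float = RESIDUAL_TOL,
    positivity_tol: float = POSITIVITY_TOL,
) -> SteadyStateSolutionSet:
    """Solve ``f(x; a*) = 0`` after clearing denominators and classify solutions.

    Flags real solutions (``|imag| < tol``) and strictly positive ones
    (all coordinates ``> positivity_tol``); each real nonnegative solution
    gets a Routh-Hurwitz stability verdict.  Candidates lying on a cleared
    denominator's zero set are artifacts of clearing and are excluded; a
    real positive candidate doing so raises :class:`DenominatorCollisionError`.
    """
    polys, den_exprs, subs = _substituted_polynomials(sys, a_star)
    sols = _solve_polynomial_system(polys, sys.variables)

    J = jacobian(sys).subs(subs)
    poly_funcs = [sp.lambdify(sys.variables, p, "numpy") for p in polys]
    den_funcs = [sp.lambdify(sys.variables, d, "numpy") for d in den_exprs]

    result = SteadyStateSolutionSet(tol=tol)
    for coords in sols:
        den_vals = [complex(f(*coords)) for f in den_funcs]
        residual = max(abs(complex(f(*coords))) for f in poly_funcs)
        is_real = all(abs(c.imag) < tol for c in coords)
        reals = tuple(c.real for c in coords)
        is_positive = is_real and all(r > positivity_tol for r in reals)
        if any(abs(d) < 1e-12 for d in den_vals):
            if is_positive:
                raise DenominatorCollisionError(
                    f"positive steady-state candidate {reals} lies on a rate denominator zero set"
                )
            continue  # spurious root introduced by clearing denominators
        state = SteadyState(
            coords=coords,
            residual=residual,
            is_real=is_real,
            is_positive=is_positive,
        )
        if is_real and all(r > -positivity_tol for r in reals):
            point = dict(zip(sys.variables, [sp.nsimplify(r, rational=True) for r in reals]))
            J_num = J.subs(point)
            try:
                cp = char_poly(J_num)
                routh = [float(r) for r in routh_polynomials(cp)]
                state.routh_values = tuple(routh)
                state.verdict = is_stable(np.array(J_num.evalf(17), dtype=float))
            except RuntimeError:
                state.verdict = BOUNDARY
        result.states.append(state)
    return result


def finite_difference_jacobian(sys: ParametricODESystem, point: Mapping, h: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian; an independent oracle for tests."""
    syms = list(sys.variables) + list(sys.parameters)
    funcs = [sp.lambdify(syms, r, "numpy") for r in sys.rates]
    base = np.array([float(point[s.name] if s.name in point else point[s]) for s in syms])
    nvar = len(sys.variables)
    out = np.zeros((len(funcs), nvar))
    for j in range(nvar):
        up, dn = base.copy(), base.copy()
        up[j] += h
        dn[j] -= h
        for i, f in enumerate(funcs):
            out[i, j] = (f(*up) - f(*dn)) / (2 * h)
    return out
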