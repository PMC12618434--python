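"""Boundary computation: singular, Routh-Hurwitz and coordinate boundaries
per equilibrium component, assembled into a hypersurface arrangement.

The equilibrium ideal of an ecological model usually splits into components,
one per equilibrium type (extinction, exclusions, coexistence), because
per-capita structure makes each rate factor as ``variable * cofactor``.
The decomposition here exploits exactly that: generators are recursively
factored and the system branches on each factor, pruning inconsistent
branches.  For each component, parameter-only boundary polynomials are then
obtained by eliminating the state variables from the component ideal plus
one extra polynomial at a time (a Routh polynomial, the Jacobian determinant,
or a coordinate), which is typically much cheaper than one monolithic
elimination.  Elimination prefers exact triangular substitution (solving
generators that are linear in a variable) with a final Sylvester resultant,
falling back to a lexicographic Groebner basis.
"""

from __future__ import annotations

import logging
import multiprocessing
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import sympy as sp

from .models import ParametricODESystem, char_poly, jacobian, routh_polynomials

__all__ = [
    "ComponentIdeal",
    "HypersurfaceArrangement",
    "EliminationResult",
    "EliminationTimeout",
    "decompose_equilibrium_ideal",
    "singular_boundary",
    "routh_hurwitz_boundary",
    "coordinate_boundary",
    "total_boundary",
    "eliminate",
    "canonical_factor",
]

logger = logging.getLogger(__name__)


class EliminationTimeout(RuntimeError):
    """An elimination call exceeded its wall-clock budget."""


# ---------------------------------------------------------------------------
# canonical polynomial form


def _grevlex_lead_coeff(poly: sp.Poly):
    def key(term):
        monom, _coeff = term
        return (sum(monom), tuple(-e for e in reversed(monom)))

    return max(poly.terms(), key=key)[1]


def canonical_factor(expr: sp.Expr, symbols: Sequence[sp.Symbol]) -> sp.Expr:
    """Canonical representative of a polynomial up to a unit multiple.

    Integer, coprime coefficients with positive leading coefficient under
    graded reverse-lex monomial order; used to deduplicate boundary factors.
    """
    poly = sp.Poly(sp.expand(expr), *symbols, domain="QQ")
    _, poly = poly.clear_denoms(convert=True)
    _, poly = poly.primitive()
    if _grevlex_lead_coeff(poly) < 0:
        poly = -poly
    return poly.as_expr()


def _factor_key(expr: sp.Expr, symbols: Sequence[sp.Symbol]):
    poly = sp.Poly(canonical_factor(expr, symbols), *symbols)
    return tuple(sorted(poly.terms()))


def _irreducible_factors(expr: sp.Expr, symbols: Sequence[sp.Symbol]) -> list[sp.Expr]:
    """Nonconstant squarefree irreducible factors over Q, canonicalized."""
    expr = sp.cancel(sp.together(expr))
    num, _ = sp.fraction(expr)
    if num == 0:
        return []
    _, factors = sp.factor_list(sp.expand(num), *symbols)
    out = []
    for base, _mult in factors:
        if base.free_symbols & set(symbols):
            out.append(canonical_factor(base, symbols))
    return out


# ---------------------------------------------------------------------------
# component ideals


@dataclass(frozen=True)
class ComponentIdeal:
    """One component of the equilibrium ideal.

    ``zero_coords`` are the state variables identically zero on the component;
    the ``label`` encodes the equilibrium type by its nonzero-coordinate
    pattern (``E_0`` all-zero, ``E_co`` none forced zero, else ``E_`` plus the
    names of the surviving coordinates, e.g. ``E_xy``).
    """

    generators: tuple[sp.Expr, ...]
    zero_coords: frozenset[sp.Symbol]
    label: str
    variables: tuple[sp.Symbol, ...]
    parameters: tuple[sp.Symbol, ...]

    def groebner(self):
        return sp.groebner(
            [sp.expand(g) for g in self.generators],
            *self.variables,
            *self.parameters,
            order="grevlex",
        )


def _component_label(zero_coords, variables) -> str:
    nonzero = [v for v in variables if v not in zero_coords]
    if not nonzero:
        return "E_0"
    if len(nonzero) == len(variables):
        return "E_co"
    return "E_" + "".join(v.name[0] for v in nonzero)


def _groebner_key(gens, symbols):
    G = sp.groebner([sp.expand(g) for g in gens], *symbols, order="grevlex")
    return tuple(sorted(_factor_key(g, symbols) for g in G.exprs))


def decompose_equilibrium_ideal(
    sys: ParametricODESystem, drop_denominator_components: bool = True
) -> list[ComponentIdeal]:
    """Split the equilibrium ideal into components by recursive factoring.

    Each generator that factors as ``u * v`` (after substituting coordinates
    already forced to zero on the branch) splits the branch into ``u = 0`` and
    ``v = 0``; inconsistent branches are pruned, duplicate and redundant
    (variety-contained) components removed.  Components lying inside a rate
    denominator's zero set are artifacts of clearing denominators and are
    dropped when ``drop_denominator_components`` is set.
    """
    nums, dens = sys.polynomial_rates()
    symbols = list(sys.variables) + list(sys.parameters)
    var_set = set(sys.variables)
    branches: list[list[sp.Expr]] = []

    def reduce_gen(gen, zero):
        return sp.expand(gen.subs({v: 0 for v in zero}))

    def split(pending, chosen, zero):
        pending = [p for p in (reduce_gen(g, zero) for g in pending) if p != 0]
        if not pending:
            branches.append(list(chosen))
            return
        # prefer a generator that actually factors so later generators can be
        # reduced modulo the new zero coordinates before factoring
        factored = [(i, sp.factor_list(p, *symbols)[1]) for i, p in enumerate(pending)]
        idx, factors = max(factored, key=lambda t: len(t[1]))
        rest = [p for i, p in enumerate(pending) if i != idx]
        seen = set()
        for base, _mult in factors:
            if not base.free_symbols & set(sys.variables):
                # constant in the variables: a unit over C(a); branching on a
                # parameter-only factor would create a non-generic component
                continue
            base = canonical_factor(base, symbols)
            key = _factor_key(base, symbols)
            if key in seen:
                continue
            seen.add(key)
            new_zero = set(zero)
            if base in var_set:
                new_zero.add(base)
            split(rest, chosen + [base], new_zero)

    split(list(nums), [], set())

    den_factors = []
    for den in dens:
        den_factors.extend(_irreducible_factors(den, symbols))

    components: list[ComponentIdeal] = []
    seen_keys = {}
    for gens in branches:
        G = sp.groebner([sp.expand(g) for g in gens], *symbols, order="grevlex")
        if list(G.exprs) == [sp.Integer(1)]:
            continue  # inconsistent branch
        if drop_denominator_components and any(
            G.reduce(d)[1] == 0 for d in den_factors
        ):
            continue  # component lives inside a denominator zero set
        key = tuple(sorted(_factor_key(g, symbols) for g in G.exprs))
        if key in seen_keys:
            continue
        zero = frozenset(v for v in sys.variables if G.reduce(v)[1] == 0)
        for g in gens:
            reduced = reduce_gen(g, zero)
            if reduced != 0 and len(sp.factor_list(reduced, *symbols)[1]) > 1:
                warnings.warn(
                    f"component {gens} keeps a reducible generator {g}; "
                    "returning it as a single (possibly mixed) component"
                )
        comp = ComponentIdeal(
            generators=tuple(gens),
            zero_coords=zero,
            label=_component_label(zero, sys.variables),
            variables=sys.variables,
            parameters=sys.parameters,
        )
        seen_keys[key] = comp
        components.append(comp)

    # remove components whose variety is contained in another's
    redundant = set()
    bases = {id(c): c.groebner() for c in components}
    for a in components:
        for b in components:
            if a is b or id(b) in redundant or id(a) in redundant:
                continue
            G_b = bases[id(b)]
            if all(G_b.reduce(g)[1] == 0 for g in a.generators):
                # I_a subseteq I_b so V(b) subseteq V(a): b is redundant
                redundant.add(id(b))
    return [c for c in components if id(c) not in redundant]


# ---------------------------------------------------------------------------
# elimination


@dataclass
class EliminationResult:
    """Outcome of eliminating the state variables from an augmented ideal.

    ``kind`` is one of ``hypersurface`` (codimension-1 factors found),
    ``zero`` (the zero ideal: every parameter value admits a solution),
    ``codim_ge_2`` (elimination ideal has codimension > 1; no hypersurface),
    or ``empty`` (augmented system inconsistent: no boundary at all).
    """

    factors: list[sp.Expr]
    kind: str

    def __iter__(self):
        return iter(self.factors)


def _triangular_reduce(polys, elim_vars):
    """Solve generators that are linear in a variable and substitute.

    Valid on an irreducible component where the pivot coefficient is not
    identically zero; returns (leftover polynomials, unresolved variables).
    """
    work = [sp.cancel(sp.together(p)) for p in polys]
    remaining = list(elim_vars)
    changed = True
    while changed and remaining:
        changed = False
        for i, p in enumerate(work):
            num, _ = sp.fraction(p)
            for v in remaining:
                if sp.degree(num, v) != 1:
                    continue
                poly_v = sp.Poly(num, v)
                A, B = poly_v.coeff_monomial(v), poly_v.coeff_monomial(1)
                B = num - A * v
                if A == 0 or A.free_symbols & set(remaining):
                    continue
                sol = sp.cancel(-B / A)
                work = [sp.cancel(q.subs(v, sol)) for j, q in enumerate(work) if j != i]
                remaining.remove(v)
                changed = True
                break
            if changed:
                break
    leftovers = []
    for p in work:
        num, _ = sp.fraction(sp.cancel(sp.together(p)))
        if sp.expand(num) != 0:
            leftovers.append(sp.expand(num))
    return leftovers, remaining


def _eliminate_groebner(polys, elim_vars, params):
    G = sp.groebner(
        [sp.expand(p) for p in polys], *elim_vars, *params, order="lex"
    )
    exprs = list(G.exprs)
    if exprs == [sp.Integer(1)]:
        return EliminationResult([], "empty")
    elim = [g for g in exprs if g.free_symbols.isdisjoint(elim_vars)]
    return _pack_elimination(elim, params)


def _pack_elimination(param_polys, params):
    param_polys = [sp.expand(p) for p in param_polys if sp.expand(p) != 0]
    if not param_polys:
        return EliminationResult([], "zero")
    if any(not p.free_symbols for p in param_polys):
        return EliminationResult([], "empty")
    g = param_polys[0]
    for q in param_polys[1:]:
        g = sp.gcd(g, q)
    if not g.free_symbols & set(params):
        logger.info("elimination ideal has codimension >= 2; no hypersurface contributed")
        return EliminationResult([], "codim_ge_2")
    return EliminationResult(_irreducible_factors(g, params), "hypersurface")


def eliminate(
    polys: Sequence[sp.Expr],
    elim_vars: Sequence[sp.Symbol],
    params: Sequence[sp.Symbol],
    method: str = "auto",
) -> EliminationResult:
    """Parameter-only consequences of ``polys``: the elimination ideal's
    codimension-1 part as a list of irreducible factors over Q.

    ``method='auto'`` solves triangular (variable-linear) generators by exact
    substitution, eliminates one leftover variable by a Sylvester resultant,
    and falls back to a block-lex Groebner basis otherwise.
    """
    elim_vars = [v for v in elim_vars if any(v in p.free_symbols for p in polys)]
    if not elim_vars:
        return _pack_elimination([sp.fraction(sp.cancel(sp.together(p)))[0] for p in polys], params)
    if method == "groebner":
        return _eliminate_groebner(polys, elim_vars, params)

    leftovers, remaining = _triangular_reduce(polys, elim_vars)
    if not remaining:
        return _pack_elimination(leftovers, params)
    if len(remaining) == 1:
        v = remaining[0]
        with_v = [p for p in leftovers if v in p.free_symbols]
        without_v = [p for p in leftovers if v not in p.free_symbols]
        if not with_v:
            return _pack_elimination(without_v, params)
        if len(with_v) == 1 and not without_v:
            # a single polynomial of positive degree in v is generically
            # solvable over C: the projection closure is everything
            return EliminationResult([], "zero")
        pivot = min(with_v, key=lambda p: sp.degree(p, v))
        resultants = []
        for q in with_v:
            if q is pivot:
                continue
            res = sp.resultant(sp.Poly(pivot, v), sp.Poly(q, v))
            if sp.expand(res if isinstance(res, sp.Expr) else res.as_expr()) == 0:
                return _eliminate_groebner(polys, elim_vars, params)
            resultants.append(res if isinstance(res, sp.Expr) else res.as_expr())
        return _pack_elimination(resultants + without_v, params)
    return _eliminate_groebner(polys, elim_vars, params)


def _eliminate_entry(conn, polys, elim_vars, params, method):
    try:
        conn.send(eliminate(polys, elim_vars, params, method))
    except Exception as exc:  # pragma: no cover - transport only
        conn.send(exc)
    finally:
        conn.close()


def eliminate_with_timeout(polys, elim_vars, params, method="auto", timeout=None, context=""):
    """Run :func:`eliminate` with an optional wall-clock cap in seconds."""
    if timeout is None:
        return eliminate(polys, elim_vars, params, method)
    ctx = multiprocessing.get_context("fork")
    parent, child = ctx.Pipe()
    proc = ctx.Process(target=_eliminate_entry, args=(child, list(polys), list(elim_vars), list(params), method))
    proc.start()
    if parent.poll(timeout):
        result = parent.recv()
        proc.join()
        if isinstance(result, Exception):
            raise result
        return result
    proc.terminate()
    proc.join()
    raise EliminationTimeout(f"elimination timed out after {timeout}s ({context})")


# ---------------------------------------------------------------------------
# the three boundary types


def _routh_numerators(sys: ParametricODESystem) -> list[sp.Expr]:
    cp = char_poly(jacobian(sys))
    nums = []
    for r in routh_polynomials(cp):
        num, _ = sp.fraction(sp.cancel(sp.together(r)))
        nums.append(sp.expand(num))
    return nums


def singular_boundary(
    comp: ComponentIdeal, sys: ParametricODESystem, method="auto", timeout=None
) -> list[sp.Expr]:
    """Irreducible factors of the singular (discriminant) boundary of a component:
    eliminate the variables from the component ideal plus ``det(J)``."""
    det = sp.cancel(jacobian(sys).det())
    num, _ = sp.fraction(sp.together(det))
    result = eliminate_with_timeout(
        list(comp.generators) + [sp.expand(num)],
        sys.variables,
        sys.parameters,
        method,
        timeout,
        context=f"singular boundary of {comp.label}",
    )
    return result.factors


def routh_hurwitz_boundary(
    comp: ComponentIdeal, sys: ParametricODESystem, method="auto", timeout=None
) -> list[sp.Expr]:
    """Irreducible factors of the stability boundary of a component.

    Processed one Routh polynomial at a time (an easier elimination than the
    full product) and unioned.
    """
    factors = {}
    for r_num in _routh_numerators(sys):
        result = eliminate_with_timeout(
            list(comp.generators) + [r_num],
            sys.variables,
            sys.parameters,
            method,
            timeout,
            context=f"Routh-Hurwitz boundary of {comp.label}",
        )
        for f in result.factors:
            factors[_factor_key(f, sys.parameters)] = f
    return list(factors.values())


def coordinate_boundary(
    comp: ComponentIdeal,
    variable,
    sys: ParametricODESystem | None = None,
    method="auto",
    timeout=None,
) -> EliminationResult:
    """Factors of the coordinate boundary for one variable on one component.

    Returns the ``zero``-kind sentinel (and no factors) when the variable is
    identically zero on the component: every parameter value then admits such
    a solution, so the coordinate boundary carries no information.
    """
    var = variable if isinstance(variable, sp.Symbol) else sp.Symbol(str(variable))
    if var in comp.zero_coords:
        return EliminationResult([], "zero")
    return eliminate_with_timeout(
        list(comp.generators) + [var],
        comp.variables,
        comp.parameters,
        method,
        timeout,
        context=f"{var} coordinate boundary of {comp.label}",
    )


# ---------------------------------------------------------------------------
# hypersurface arrangements


@dataclass
class HypersurfaceArrangement:
    """Distinct irreducible boundary polynomials in the parameters.

    ``is_coordinate[i]`` marks polynomials that are bare parameter coordinate
    hyperplanes; ``provenance`` maps each polynomial index to the
    (component label, boundary type) pairs that produced it.
    """

    parameters: tuple[sp.Symbol, ...]
    polynomials: list[sp.Expr]
    is_coordinate: list[bool] = field(default_factory=list)
    provenance: dict[int, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.is_coordinate:
            self.is_coordinate = [
                poly in set(self.parameters) for poly in self.polynomials
            ]

    @classmethod
    def from_polynomials(
        cls,
        parameters: Sequence[sp.Symbol],
        polynomials: Iterable[sp.Expr],
        provenance: Mapping[int, list[tuple[str, str]]] | None = None,
    ) -> "HypersurfaceArrangement":
        """Normalize user polynomials: squarefree irreducible factors, deduped."""
        params = tuple(parameters)
        seen = {}
        prov: dict[int, list[tuple[str, str]]] = {}
        source = provenance or {}
        for i, poly in enumerate(polynomials):
            for f in _irreducible_factors(poly, params):
                key = _factor_key(f, params)
                if key not in seen:
                    seen[key] = f
                    prov[len(seen) - 1] = list(source.get(i, []))
                else:
                    idx = list(seen).index(key)
                    for tag in source.get(i, []):
                        if tag not in prov[idx]:
                            prov[idx].append(tag)
        polys = list(seen.values())
        return cls(
            parameters=params,
            polynomials=polys,
            is_coordinate=[p in set(params) for p in polys],
            provenance=prov,
        )

    @property
    def m(self) -> int:
        return len(self.polynomials)

    @property
    def degrees(self) -> list[int]:
        return [int(sp.total_degree(p, *self.parameters)) for p in self.polynomials]

    def boundary_factors(self) -> list[sp.Expr]:
        """The non-coordinate-hyperplane factors."""
        return [p for p, c in zip(self.polynomials, self.is_coordinate) if not c]

    def with_coordinate_hyperplanes(self) -> "HypersurfaceArrangement":
        """Append any missing parameter coordinate hyperplanes."""
        missing = [p for p in self.parameters if p not in set(self.polynomials)]
        arr = HypersurfaceArrangement(
            parameters=self.parameters,
            polynomials=self.polynomials + missing,
            is_coordinate=self.is_coordinate + [True] * len(missing),
            provenance={
                **self.provenance,
                **{
                    self.m + i: [("*", "coordinate_hyperplane")]
                    for i in range(len(missing))
                },
            },
        )
        return arr

    def positive_orthant_relevant(self) -> "HypersurfaceArrangement":
        """Drop factors with no zeros in the open positive orthant.

        A polynomial whose nonzero coefficients all share one sign cannot
        vanish for strictly positive parameters, so it contributes no wall
        to the positive-orthant decomposition; dropping it leaves the
        regions unchanged while reducing the routing-function degree.
        """
        keep, prov = [], {}
        for i, poly in enumerate(self.polynomials):
            coeffs = sp.Poly(poly, *self.parameters).coeffs()
            if all(c > 0 for c in coeffs) or all(c < 0 for c in coeffs):
                continue
            prov[len(keep)] = self.provenance.get(i, [])
            keep.append(poly)
        return HypersurfaceArrangement(
            parameters=self.parameters,
            polynomials=keep,
            is_coordinate=[p in set(self.parameters) for p in keep],
            provenance=prov,
        )

    def substitute(self, substitutions: Mapping) -> "HypersurfaceArrangement":
        """Restrict to a slice by substituting exact values for some parameters.

        Factors that become constant are dropped; a factor that becomes
        identically zero means the slice lies inside that boundary stratum and
        is dropped with a warning.
        """
        by_name = {p.name: p for p in self.parameters}
        subs = {}
        for key, value in substitutions.items():
            sym = by_name[key.name if isinstance(key, sp.Symbol) else str(key)]
            subs[sym] = sp.nsimplify(value, rational=True)
        remaining = tuple(p for p in self.parameters if p not in subs)
        polys = []
        prov = {}
        for i, poly in enumerate(self.polynomials):
            restricted = sp.expand(poly.subs(subs))
            if restricted == 0:
                warnings.warn(
                    f"boundary factor {poly} vanishes identically on the slice; dropped"
                )
                continue
            if not restricted.free_symbols & set(remaining):
                continue
            prov[len(polys)] = self.provenance.get(i, [])
            polys.append(restricted)
        return HypersurfaceArrangement.from_polynomials(remaining, polys, prov)


@dataclass
class BoundaryFailure:
    component: str
    boundary_type: str
    error: Exception


def total_boundary(
    sys: ParametricODESystem,
    include_coordinate_hyperplanes: bool = True,
    components: Sequence[ComponentIdeal] | None = None,
    method: str = "auto",
    timeout: float | None = None,
) -> HypersurfaceArrangement:
    """Assemble the total boundary of a model as a hypersurface arrangement.

    Unions the singular, Routh-Hurwitz and coordinate boundary factors over
    all equilibrium components, deduplicated up to unit multiples; parameter
    coordinate hyperplanes are appended when requested (the positive-orthant
    convention).  Per-component elimination timeouts are collected and
    re-raised with the failing component named.
    """
    comps = list(components) if components is not None else decompose_equilibrium_ideal(sys)
    factors: list[sp.Expr] = []
    provenance: dict[int, list[tuple[str, str]]] = {}
    failures: list[BoundaryFailure] = []

    def add(fs, label, btype):
        for f in fs:
            factors.append(f)
            provenance[len(factors) - 1] = [(label, btype)]

    for comp in comps:
        try:
            add(singular_boundary(comp, sys, method, timeout), comp.label, "singular")
        except EliminationTimeout as exc:
            failures.append(BoundaryFailure(comp.label, "singular", exc))
        try:
            add(routh_hurwitz_boundary(comp, sys, method, timeout), comp.label, "routh_hurwitz")
        except EliminationTimeout as exc:
            failures.append(BoundaryFailure(comp.label, "routh_hurwitz", exc))
        for var in sys.variables:
            if var in comp.zero_coords:
                continue
            try:
                result = coordinate_boundary(comp, var, sys, method, timeout)
                add(result.factors, comp.label, f"coordinate_{var.name}")
            except EliminationTimeout as exc:
                failures.append(BoundaryFailure(comp.label, f"coordinate_{var.name}", exc))

    if failures:
        detail = "; ".join(f"{f.component}/{f.boundary_type}" for f in failures)
        raise EliminationTimeout(f"boundary eliminations timed out for: {detail}")

    arr = HypersurfaceArrangement.from_polynomials(sys.parameters, factors, provenance)
    if include_coordinate_hyperplanes:
        arr = arr.with_coordinate_hyperplanes()
    return arr
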