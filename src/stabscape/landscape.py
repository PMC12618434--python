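"""Region classification: label each connected region of parameter space by
its set of stable steady-state types, and produce 2-D stability-landscape
slices.

Equilibrium types are named by their nonzero-coordinate pattern (``E_0``
total extinction, ``E_x`` host only, ``E_xy`` mutualist exclusion, ``E_xz``
parasite exclusion, ``E_co`` full coexistence for a three-species model).
Within one region of the complement of the total boundary, the number and
type of stable steady states cannot change, so classifying the routing point
of each region classifies the whole region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from . import models
from .boundaries import (
    ComponentIdeal,
    HypersurfaceArrangement,
    decompose_equilibrium_ideal,
    total_boundary,
)
from .connectivity import RoutingGraph, build_routing_graph, locate
from .models import ParametricODESystem, jacobian
from .routing import routing_points

__all__ = [
    "StableStateSet",
    "RegionReport",
    "SliceResult",
    "ComponentSolver",
    "classify_region",
    "landscape_slice",
    "detect_limit_cycle_region",
]

_DISPLAY_NAMES = {
    "E_0": "Total extinction",
    "E_x": "Coral only",
    "E_xy": "Mutualist exclusion",
    "E_xz": "Pathogen exclusion",
    "E_co": "Coexistence",
}

_COLOR_KEY = {
    frozenset(): "#ffffff",
    frozenset({"E_0"}): "#4d4d4d",
    frozenset({"E_x"}): "#f2a900",
    frozenset({"E_xy"}): "#9467bd",
    frozenset({"E_xz"}): "#2ca02c",
    frozenset({"E_co"}): "#1f77b4",
    frozenset({"E_0", "E_xy"}): "#c5b0d5",
    frozenset({"E_0", "E_xz"}): "#98df8a",
    frozenset({"E_0", "E_co"}): "#aec7e8",
    frozenset({"E_x", "E_xz"}): "#bcbd22",
    frozenset({"E_x", "E_co"}): "#17becf",
}


@dataclass(frozen=True)
class StableStateSet:
    """A set of stable equilibrium-type labels with its display vocabulary.

    Keyed by the label set itself; display names are cosmetic and generated
    from the singleton names (an empty set flags possible limit cycles).
    """

    labels: frozenset[str]

    @property
    def display_name(self) -> str:
        if not self.labels:
            return "No stable steady state (possible limit cycle)"
        names = [_DISPLAY_NAMES.get(l, l) for l in sorted(self.labels)]
        return " or ".join(names)

    @property
    def color(self) -> str:
        return _COLOR_KEY.get(self.labels, "#cccccc")

    @property
    def bistable(self) -> bool:
        return len(self.labels) >= 2

    def serialize(self) -> str:
        return "|".join(sorted(self.labels))

    @classmethod
    def deserialize(cls, text: str) -> "StableStateSet":
        return cls(frozenset(x for x in text.split("|") if x))

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)


class ComponentSolver:
    """Fast numeric steady-state solver for one equilibrium component.

    Performs the triangular reduction of the component generators once,
    symbolically (variables appearing linearly are solved and substituted,
    at most one variable is left in a final univariate polynomial), then
    evaluates numerically per parameter point via polynomial root finding.
    """

    def __init__(self, comp: ComponentIdeal, sys: ParametricODESystem):
        self.comp = comp
        self.sys = sys
        self.variables = sys.variables
        self.parameters = sys.parameters
        gens = [sp.expand(g.subs({v: 0 for v in comp.zero_coords})) for g in comp.generators]
        gens = [g for g in gens if g != 0]
        free_vars = [v for v in self.variables if v not in comp.zero_coords]

        solved: list[tuple[sp.Symbol, sp.Expr]] = []
        work = [sp.cancel(g) for g in gens]
        remaining = list(free_vars)
        changed = True
        while changed and remaining:
            changed = False
            for i, p in enumerate(work):
                num, _ = sp.fraction(sp.cancel(sp.together(p)))
                for v in remaining:
                    if sp.degree(num, v) != 1:
                        continue
                    A = sp.Poly(num, v).coeff_monomial(v)
                    if A == 0 or A.free_symbols & set(remaining):
                        continue
                    B = num - A * v
                    sol = sp.cancel(-B / A)
                    solved.append((v, sol))
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
        if len(remaining) > 1 or (remaining and not leftovers):
            raise NotImplementedError(
                f"component {comp.label} is not triangular; use models.steady_states"
            )
        self._solved = solved
        self._final_var = remaining[0] if remaining else None
        if self._final_var is not None:
            poly = sp.Poly(leftovers[0], self._final_var)
            self._final_coeffs = sp.lambdify(self.parameters, poly.all_coeffs(), "numpy")
            self._extra = [
                sp.lambdify(list(self.parameters) + [self._final_var], l, "numpy")
                for l in leftovers[1:]
            ]
        else:
            self._final_coeffs = None
            self._extra = [sp.lambdify(self.parameters, l, "numpy") for l in leftovers]
        # back-substitution functions, evaluated in reverse solve order
        self._solved_funcs = []
        for v, expr in solved:
            args = list(self.parameters) + [u for u, _ in solved] + (
                [self._final_var] if self._final_var is not None else []
            )
            self._solved_funcs.append((v, sp.lambdify(args, expr, "numpy")))

    def solve(self, a_star: Sequence[float]) -> list[tuple[complex, ...]]:
        """All complex solutions of the component at one parameter point."""
        a = [float(x) for x in a_star]
        if self._final_var is not None:
            coeffs = np.array(self._final_coeffs(*a), dtype=complex)
            coeffs = np.trim_zeros(coeffs, "f")
            if coeffs.size == 0:
                return []
            roots = np.roots(coeffs) if coeffs.size > 1 else np.array([])
            roots = [
                r
                for r in roots
                if all(abs(complex(f(*a, r))) < 1e-8 for f in self._extra)
            ]
        else:
            if any(abs(complex(f(*a))) > 1e-10 for f in self._extra):
                return []
            roots = [None]
        out = []
        for root in roots:
            values: dict[sp.Symbol, complex] = {v: 0.0 for v in self.comp.zero_coords}
            if self._final_var is not None:
                values[self._final_var] = complex(root)
            for v, func in reversed(self._solved_funcs):
                args = a + [complex(values.get(u, 0.0)) for u, _ in self._solved] + (
                    [complex(values.get(self._final_var, 0.0))]
                    if self._final_var is not None
                    else []
                )
                values[v] = complex(func(*args))
            out.append(tuple(complex(values[v]) for v in self.variables))
        return out


@dataclass
class RegionReport:
    """Classification of one connected region of parameter space."""

    region_id: int
    parameters: tuple[sp.Symbol, ...]
    representative: tuple[float, ...]
    n_real_positive: int
    stable_set: StableStateSet
    counts_by_label: dict[str, int] = field(default_factory=dict)
    near_boundary: bool = False

    @property
    def bistable(self) -> bool:
        return self.stable_set.bistable

    @property
    def empty_stable_set(self) -> bool:
        return len(self.stable_set) == 0


def _classify_at(
    sys: ParametricODESystem,
    solvers: list[ComponentSolver],
    J_funcs,
    a_star: Sequence[float],
    tol: float = 1e-9,
):
    """Solve all components at one parameter point and classify stability."""
    a = [float(x) for x in a_star]
    stable_labels = set()
    counts: dict[str, int] = {}
    n_positive = 0
    near_boundary = False
    for solver in solvers:
        comp = solver.comp
        free_vars = [v for v in sys.variables if v not in comp.zero_coords]
        for coords in solver.solve(a):
            if any(abs(c.imag) > 1e-8 for c in coords):
                continue
            reals = [c.real for c in coords]
            free_values = [r for v, r in zip(sys.variables, reals) if v in free_vars]
            if any(r < -tol for r in free_values):
                continue
            if any(abs(r) <= tol for r in free_values):
                near_boundary = True  # zero where the type demands positive
                continue
            counts[comp.label] = counts.get(comp.label, 0) + 1
            n_positive += 1
            J = np.array([[f(*a, *reals) for f in row] for row in J_funcs], dtype=float)
            verdict = models.is_stable(J)
            if verdict == models.STABLE:
                stable_labels.add(comp.label)
            elif verdict == models.BOUNDARY:
                near_boundary = True
    return StableStateSet(frozenset(stable_labels)), counts, n_positive, near_boundary


def classify_region(
    sys: ParametricODESystem,
    a_star: Sequence[float] | Mapping,
    components: Sequence[ComponentIdeal] | None = None,
    tol: float = 1e-9,
) -> tuple[StableStateSet, dict[str, int]]:
    """Stable steady-state set and per-type counts at one parameter point.

    Steady states are solved per equilibrium component, assigned their type
    by zero-coordinate pattern, and tested for stability with the
    Routh-Hurwitz criterion.  A steady state within tolerance of a boundary
    classification (zero coordinate or zero Routh value) flags the region
    "near-boundary" rather than being misclassified.
    """
    if isinstance(a_star, Mapping):
        by_name = {p.name: p for p in sys.parameters}
        values = {by_name[str(k)]: v for k, v in a_star.items()}
        a_star = [float(values[p]) for p in sys.parameters]
    comps = list(components) if components is not None else decompose_equilibrium_ideal(sys)
    solvers = [ComponentSolver(c, sys) for c in comps]
    J_funcs = _jacobian_functions(sys)
    stable_set, counts, _, near = _classify_at(sys, solvers, J_funcs, a_star, tol)
    if near:
        warnings.warn(f"steady state near a boundary classification at {a_star}")
    return stable_set, counts


def _jacobian_functions(sys: ParametricODESystem):
    J = jacobian(sys)
    args = list(sys.parameters) + list(sys.variables)
    return [[sp.lambdify(args, entry, "numpy") for entry in row] for row in J.tolist()]


@dataclass
class SliceResult:
    """Full output of a 2-D landscape slice computation."""

    reports: list[RegionReport]
    arrangement: HypersurfaceArrangement
    rf: object
    graph: RoutingGraph
    system: ParametricODESystem

    def __iter__(self):
        return iter(self.reports)

    def __len__(self):
        return len(self.reports)


def landscape_slice(
    sys: ParametricODESystem | None,
    fixed: Mapping | None = None,
    free: Sequence[str] | None = None,
    window=((0, 10), (0, 10)),
    seed: int = 0,
    arrangement: HypersurfaceArrangement | None = None,
    components: Sequence[ComponentIdeal] | None = None,
    validate: int = 0,
    elimination_timeout: float | None = None,
) -> SliceResult:
    """Compute a 2-D stability-landscape slice: fix parameters to exact
    rationals, run the full pipeline (boundary -> routing function -> routing
    points -> graph), and classify each region at its routing point.

    ``validate`` > 0 additionally samples that many interior points per region
    (rejection from a box around the routing point, confirmed by ``locate``)
    and checks the classification is constant; discrepancies mark the region
    near-boundary.
    """
    if sys is None:
        # degenerate use: a raw arrangement with no ODE behind it; regions
        # are enumerated but steady-state classification is skipped
        if arrangement is None:
            raise ValueError("need either a system or an arrangement")
        sliced = None
        comps = []
        arr = arrangement
    else:
        sliced = sys.fix(fixed) if fixed else sys
        if free is not None:
            names = [p.name for p in sliced.parameters]
            if sorted(names) != sorted(str(f) for f in free):
                raise ValueError(f"free parameters are {names}, requested {list(free)}")
        if sliced.k != 2:
            raise ValueError(f"a slice needs exactly 2 free parameters, got {sliced.k}")

        comps = (
            list(components)
            if components is not None
            else decompose_equilibrium_ideal(sliced)
        )
        if arrangement is None:
            arr = total_boundary(
                sliced, include_coordinate_hyperplanes=True, components=comps,
                timeout=elimination_timeout,
            )
        else:
            arr = arrangement
            missing = set(p.name for p in arr.parameters) - set(p.name for p in sliced.parameters)
            if missing:
                raise ValueError(f"arrangement has extra parameters {missing}")

    hi = 1.5 * max(float(w[1]) for w in window)
    # factors with no positive-orthant zeros contribute no wall; dropping
    # them keeps the routing-function degree manageable (coordinate factors
    # are re-added by the routing constructor)
    routing_arr = arr.positive_orthant_relevant()
    rf, points, _report = routing_points(
        routing_arr, seed=seed, restrict_positive=True, box=[(1e-8, hi)] * 2
    )
    graph = build_routing_graph(rf, points)

    classify = sliced is not None and bool(comps)
    solvers = [ComponentSolver(c, sliced) for c in comps] if classify else []
    J_funcs = _jacobian_functions(sliced) if classify else []

    rng = np.random.default_rng(seed)
    reports = []
    for cid, rep_idx in enumerate(graph.representatives):
        rep = graph.vertices[rep_idx].coords
        if not classify:
            reports.append(
                RegionReport(
                    region_id=cid,
                    parameters=arr.parameters,
                    representative=tuple(float(x) for x in rep),
                    n_real_positive=0,
                    stable_set=StableStateSet(frozenset()),
                )
            )
            continue
        stable_set, counts, n_pos, near = _classify_at(sliced, solvers, J_funcs, rep)
        if validate:
            near = near or not _validate_region(
                sliced, solvers, J_funcs, rf, graph, cid, rep, stable_set, n_pos,
                validate, rng,
            )
        reports.append(
            RegionReport(
                region_id=cid,
                parameters=sliced.parameters,
                representative=tuple(float(x) for x in rep),
                n_real_positive=n_pos,
                stable_set=stable_set,
                counts_by_label=counts,
                near_boundary=near,
            )
        )
    return SliceResult(reports=reports, arrangement=arr, rf=rf, graph=graph, system=sliced)


def _validate_region(
    sys, solvers, J_funcs, rf, graph, cid, rep, stable_set, n_pos, n_samples, rng
) -> bool:
    """Check (count, stable set) constancy at locate-confirmed interior samples."""
    accepted = 0
    attempts = 0
    scale = 0.25 * (1 + np.linalg.norm(rep))
    while accepted < n_samples and attempts < 20 * n_samples:
        attempts += 1
        sample = np.asarray(rep) + rng.uniform(-scale, scale, size=len(rep))
        if np.any(sample <= 0):
            continue
        try:
            if locate(rf, graph, sample) != cid:
                continue
        except (ValueError, RuntimeError):
            continue
        accepted += 1
        s_set, _c, s_pos, _n = _classify_at(sys, solvers, J_funcs, sample)
        if s_set != stable_set or s_pos != n_pos:
            return False
    return True


@dataclass
class LimitCycleEvidence:
    """Numerical evidence record for a no-stable-state region.

    Evidence only, not proof: reports boundedness, non-convergence to any
    steady state, and a recurrence statistic (how closely the tail of the
    trajectory returns to its final state after a time gap).
    """

    bounded: bool
    converged: bool
    converged_to: tuple[float, ...] | None
    min_steady_state_distance: float
    recurrence_distance: float
    final_state: tuple[float, ...]
    diverged: bool = False


def detect_limit_cycle_region(
    sys: ParametricODESystem,
    a_star: Sequence[float] | Mapping,
    x0: Sequence[float],
    horizon: float = 2000.0,
    components: Sequence[ComponentIdeal] | None = None,
) -> LimitCycleEvidence:
    """Integrate the ODE from ``x0`` and summarize the long-run behaviour.

    For a region whose stable set is empty, a bounded non-convergent
    trajectory with a small recurrence distance is consistent with a limit
    cycle (or a more complex attractor).
    """
    if isinstance(a_star, Mapping):
        by_name = {p.name: p for p in sys.parameters}
        a_star = [float(a_star[p.name] if p.name in a_star else a_star[p]) for p in sys.parameters]
    a = [float(x) for x in a_star]
    args = list(sys.parameters) + list(sys.variables)
    funcs = [sp.lambdify(args, r, "numpy") for r in sys.rates]

    def rhs(_t, x):
        return [f(*a, *x) for f in funcs]

    t_eval = np.linspace(0, horizon, 4001)
    sol = solve_ivp(rhs, (0, horizon), [float(v) for v in x0], t_eval=t_eval,
                    method="LSODA", rtol=1e-9, atol=1e-12)
    traj = sol.y.T
    final = traj[-1]
    max_norm = float(np.max(np.linalg.norm(traj, axis=1)))
    diverged = (not sol.success) or max_norm > 1e6
    bounded = not diverged and max_norm < 1e3

    comps = (
        list(components)
        if components is not None
        else decompose_equilibrium_ideal(sys)
    )
    steady = []
    for comp in comps:
        try:
            solver = ComponentSolver(comp, sys)
        except NotImplementedError:
            continue
        for coords in solver.solve(a):
            if all(abs(c.imag) < 1e-8 for c in coords):
                steady.append(np.array([c.real for c in coords]))
    if steady:
        min_dist = min(float(np.linalg.norm(final - s)) for s in steady)
    else:
        min_dist = np.inf
    converged = bool(min_dist < 1e-4)
    converged_to = None
    if converged:
        nearest = min(steady, key=lambda s: np.linalg.norm(final - s))
        converged_to = tuple(float(v) for v in nearest)

    # recurrence: nearest return to the final state over the tail, excluding
    # a window just before the end
    tail = traj[len(traj) // 2 : -200]
    if len(tail):
        recurrence = float(np.min(np.linalg.norm(tail - final, axis=1)))
    else:
        recurrence = np.inf
    return LimitCycleEvidence(
        bounded=bounded,
        converged=converged,
        converged_to=converged_to,
        min_steady_state_distance=float(min_dist),
        recurrence_distance=recurrence,
        final_state=tuple(float(v) for v in final),
        diverged=diverged,
    )


def plot_slice(result: SliceResult, path, window=((0, 10), (0, 10)), resolution=150):
    """Optional raster plot: color a grid by located region id.

    Presentation only; never used for counting.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    (x0, x1), (y0, y1) = window
    xs = np.linspace(x0 + (x1 - x0) / (2 * resolution), x1, resolution)
    ys = np.linspace(y0 + (y1 - y0) / (2 * resolution), y1, resolution)
    img = np.zeros((resolution, resolution, 3))
    colors = {}
    for rep in result.reports:
        rgb = tuple(
            int(rep.stable_set.color.lstrip("#")[i : i + 2], 16) / 255 for i in (0, 2, 4)
        )
        colors[rep.region_id] = rgb
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            try:
                cid = locate(result.rf, result.graph, np.array([x, y]))
                img[i, j] = colors.get(cid, (0.8, 0.8, 0.8))
            except (ValueError, RuntimeError):
                img[i, j] = (1.0, 1.0, 1.0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img, origin="lower", extent=(x0, x1, y0, y1), aspect="auto")
    names = [p.name for p in result.system.parameters]
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
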