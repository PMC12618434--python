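"""Routing functions on hypersurface arrangements and their critical points.

A routing function for the complement of an arrangement ``g_1, ..., g_m`` in
the positive orthant is the bounded rational function

    r_c(a) = g_1(a) ... g_m(a) * prod_i a_i / (1 + sum_i (a_i - c_i)^2)^D

with a generic positive center ``c`` and ``2D`` exceeding the numerator
degree.  Its critical points ("routing points") off the arrangement
catalogue the connected components of the complement: every component
contains at least one, and index-0 points (local extrema of the matching
sign) are the component representatives.  The index of a routing point is
the number of Hessian eigenvalues sharing the sign of the function value.

Critical points solve the cleared-denominator gradient system

    (1 + sum_j (a_j - c_j)^2) * d(num)/d(a_i) - 2 D * num * (a_i - c_i) = 0,

formed by clearing the denominator once, which keeps each equation at degree
``deg(num) + 1``.  For one or two parameters the system is solved
deterministically by Sylvester resultants; otherwise (or for high degrees) by
multistart Newton from a scrambled low-discrepancy grid, with residual
polishing.  Fixture counts must be solver-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.stats.qmc as qmc
import sympy as sp

from .boundaries import HypersurfaceArrangement

__all__ = [
    "RoutingFunction",
    "RoutingPoint",
    "GenericityError",
    "GenericityReport",
    "build_routing_function",
    "critical_points",
    "classify",
    "genericity_check",
    "routing_points",
]

logger = logging.getLogger(__name__)

#: Relative deduplication tolerance after polishing.
DEDUP_TOL = 1e-8
#: Relative Hessian-eigenvalue degeneracy tolerance (genericity condition).
#: Strongly anisotropic sliver regions legitimately produce eigenvalue ratios
#: around 1e-8, so the threshold sits just above arithmetic noise.
DEGENERACY_TOL = 1e-11
#: Relative tolerance for coincident critical values (genericity condition).
VALUE_TIE_TOL = 1e-9


class GenericityError(RuntimeError):
    """A genericity condition failed for the chosen center ``c``."""


class _FactorSystem:
    """Vectorized numeric evaluation of a routing function in factored form.

    The numerator is a product of low-degree factors ``f_1 ... f_m``; with
    ``L = sum log|f_j| - D log(den)`` the gradient and Hessian follow from
    per-factor derivatives (``grad r = r grad L``,
    ``Hr = r (grad L grad L^T + HL)``), which avoids expanding the
    high-degree product and keeps every evaluation numerically stable.
    Critical points off the boundary are exactly the zeros of ``grad L``.
    """

    def __init__(self, factors, parameters, center, D):
        self.k = len(parameters)
        self.D = int(D)
        self.center = np.array([float(c) for c in center])
        self.degrees = [int(sp.total_degree(f, *parameters)) for f in factors]
        self._f = [sp.lambdify(parameters, f, "numpy") for f in factors]
        self._g = [
            [sp.lambdify(parameters, sp.diff(f, a), "numpy") for a in parameters]
            for f in factors
        ]
        self._h = [
            [
                [sp.lambdify(parameters, sp.diff(f, a, b), "numpy") for b in parameters]
                for a in parameters
            ]
            for f in factors
        ]

    def _cols(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X, [X[:, i] for i in range(self.k)]

    def factor_values(self, X) -> np.ndarray:
        X, cols = self._cols(X)
        n = X.shape[0]
        out = np.empty((n, len(self._f)))
        for j, f in enumerate(self._f):
            out[:, j] = np.broadcast_to(np.asarray(f(*cols), dtype=float), (n,))
        return out

    def den(self, X) -> np.ndarray:
        X, _ = self._cols(X)
        return 1.0 + np.sum((X - self.center) ** 2, axis=1)

    def value(self, X) -> np.ndarray:
        X, _ = self._cols(X)
        fv = self.factor_values(X)
        with np.errstate(all="ignore"):
            return np.prod(fv, axis=1) / self.den(X) ** self.D

    def sign(self, X) -> np.ndarray:
        """Sign of the routing function via factor signs (overflow-free)."""
        fv = self.factor_values(X)
        return np.prod(np.sign(fv), axis=1)

    def log_abs(self, X) -> np.ndarray:
        """``log |r|`` evaluated factor-wise; ``-inf`` on the boundary."""
        X, _ = self._cols(X)
        fv = self.factor_values(X)
        with np.errstate(divide="ignore"):
            return np.sum(np.log(np.abs(fv)), axis=1) - self.D * np.log(self.den(X))

    def _grad_parts(self, X):
        X, cols = self._cols(X)
        n = X.shape[0]
        fv = self.factor_values(X)
        grads = np.empty((n, len(self._f), self.k))
        for j in range(len(self._f)):
            for i in range(self.k):
                grads[:, j, i] = np.broadcast_to(
                    np.asarray(self._g[j][i](*cols), dtype=float), (n,)
                )
        den = self.den(X)
        dden = 2.0 * (X - self.center)
        return fv, grads, den, dden

    def log_gradient(self, X) -> np.ndarray:
        """``grad L``; poles on the boundary, zeros at the critical points."""
        X, _ = self._cols(X)
        fv, grads, den, dden = self._grad_parts(X)
        with np.errstate(all="ignore"):
            phi = np.sum(grads / fv[:, :, None], axis=1)
            phi -= self.D * dden / den[:, None]
        return phi

    def log_hessian_jacobian(self, X):
        """``(grad L, H L)`` batched; the Newton system for critical points."""
        X, cols = self._cols(X)
        n = X.shape[0]
        fv, grads, den, dden = self._grad_parts(X)
        hess = np.empty((n, len(self._f), self.k, self.k))
        for j in range(len(self._f)):
            for a in range(self.k):
                for b in range(self.k):
                    hess[:, j, a, b] = np.broadcast_to(
                        np.asarray(self._h[j][a][b](*cols), dtype=float), (n,)
                    )
        with np.errstate(all="ignore"):
            phi = np.sum(grads / fv[:, :, None], axis=1) - self.D * dden / den[:, None]
            HL = np.sum(hess / fv[:, :, None, None], axis=1)
            HL -= np.einsum("nja,njb->nab", grads / fv[:, :, None], grads / fv[:, :, None])
            eye = np.eye(self.k)
            HL -= self.D * (
                2.0 * eye[None, :, :] / den[:, None, None]
                - np.einsum("na,nb->nab", dden, dden) / den[:, None, None] ** 2
            )
        return phi, HL

    def gradient(self, X) -> np.ndarray:
        return self.value(X)[:, None] * self.log_gradient(X)

    def hessian_single(self, x) -> np.ndarray:
        phi, HL = self.log_hessian_jacobian(np.atleast_2d(x))
        r = float(self.value(x)[0])
        return r * (np.outer(phi[0], phi[0]) + HL[0])


@dataclass(frozen=True)
class RoutingFunction:
    """A routing function ``num / (1 + |a - c|^2)^D`` over an arrangement."""

    arrangement: HypersurfaceArrangement
    parameters: tuple[sp.Symbol, ...]
    center: tuple[sp.Rational, ...]
    D: int
    numerator_factors: tuple[sp.Expr, ...]
    restrict_positive: bool
    seed: int | None = None

    @property
    def k(self) -> int:
        return len(self.parameters)

    @cached_property
    def numerator(self) -> sp.Expr:
        num = sp.Integer(1)
        for f in self.numerator_factors:
            num *= f
        return num

    @cached_property
    def denominator_base(self) -> sp.Expr:
        return 1 + sum((a - c) ** 2 for a, c in zip(self.parameters, self.center))

    @cached_property
    def expr(self) -> sp.Expr:
        return self.numerator / self.denominator_base**self.D

    @cached_property
    def gradient_system(self) -> list[sp.Expr]:
        """The cleared-denominator critical equations (exact polynomials)."""
        den = self.denominator_base
        return [
            den * sp.diff(self.numerator, a) - 2 * self.D * self.numerator * (a - c)
            for a, c in zip(self.parameters, self.center)
        ]

    @cached_property
    def _fs(self) -> _FactorSystem:
        return _FactorSystem(self.numerator_factors, self.parameters, self.center, self.D)

    def value(self, point) -> float:
        return float(self._fs.value(point)[0])

    def sign_value(self, point) -> float:
        return float(self._fs.sign(point)[0])

    def log_abs(self, point) -> float:
        return float(self._fs.log_abs(point)[0])

    def gradient(self, point) -> np.ndarray:
        return self._fs.gradient(point)[0]

    def log_gradient(self, point) -> np.ndarray:
        """``grad log|r|``: same trajectories as ``sign(r) grad r`` after time
        rescaling by ``|r| > 0``, but free of overflow at high degree."""
        return self._fs.log_gradient(point)[0]

    def hessian(self, point) -> np.ndarray:
        return self._fs.hessian_single(point)

    def numerator_value(self, point) -> float:
        return float(np.prod(self._fs.factor_values(point), axis=1)[0])

    def on_boundary(self, point, tol: float = 1e-10) -> bool:
        """Whether a point lies numerically on the arrangement (or a coordinate
        hyperplane when restricted to the positive orthant)."""
        point = np.asarray(point, dtype=float)
        norm = float(np.linalg.norm(point))
        fv = self._fs.factor_values(point)[0]
        for val, deg in zip(fv, self._fs.degrees):
            if abs(val) < tol * (1 + norm) ** deg:
                return True
        if self.restrict_positive and np.any(point < tol * (1 + norm)):
            return True
        return False


@dataclass
class RoutingPoint:
    """A nondegenerate critical point of a routing function.

    ``sign`` and ``log_abs`` carry the function value in overflow-free form
    (``value = sign * exp(log_abs)`` may under/overflow for extreme regions);
    ``eigenvalues`` holds the spectrum of the scaled Hessian ``H / r``, whose
    positive eigenvalues are exactly those of ``H`` sharing the sign of ``r``.
    """

    coords: np.ndarray
    value: float
    sign: float
    log_abs: float
    gradient_residual: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    eigenvectors: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    index: int | None = None
    unstable_directions: list[np.ndarray] = field(default_factory=list)

    def __repr__(self):
        coords = np.array2string(self.coords, precision=5)
        return f"RoutingPoint({coords}, value={self.value:.3e}, index={self.index})"


def build_routing_function(
    arr: HypersurfaceArrangement,
    c=None,
    seed: int = 0,
    restrict_positive: bool = True,
    D: int | None = None,
) -> RoutingFunction:
    """Construct a routing function for the complement of ``arr``.

    The numerator is the product of the arrangement polynomials times, in
    positive-orthant mode, any parameter coordinates not already present as
    arrangement members.  ``D`` defaults to the smallest integer with ``2D``
    above the numerator degree; ``c`` is drawn uniformly from ``(0.5, 1.5)^k``
    with the given seed when not supplied, rationalized so downstream
    resultant computations stay exact.
    """
    params = arr.parameters
    if not arr.polynomials and not restrict_positive:
        raise ValueError("empty arrangement needs restrict_positive to give a nonzero numerator")
    factors = list(arr.polynomials)
    if restrict_positive:
        present = set(arr.polynomials)
        factors.extend(p for p in params if p not in present)
    degree = sum(sp.total_degree(f, *params) for f in factors)
    if D is None:
        D = degree // 2 + 1
    elif 2 * D <= degree:
        raise ValueError(f"need 2D > numerator degree {degree}, got D={D}")
    if c is None:
        rng = np.random.default_rng(seed)
        c = tuple(
            sp.Rational(int(rng.integers(2**19, 3 * 2**19)), 2**20) for _ in params
        )
    else:
        c = tuple(sp.nsimplify(ci, rational=True) for ci in c)
    return RoutingFunction(
        arrangement=arr,
        parameters=params,
        center=c,
        D=int(D),
        numerator_factors=tuple(factors),
        restrict_positive=restrict_positive,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# critical point solvers


def _dedupe(points: np.ndarray, tol: float = DEDUP_TOL) -> np.ndarray:
    kept: list[np.ndarray] = []
    for p in points:
        if not all(
            np.linalg.norm(p - q) > tol * (1 + np.linalg.norm(q)) for q in kept
        ):
            continue
        kept.append(p)
    return np.array(kept) if kept else np.empty((0, points.shape[1] if points.ndim > 1 else 0))

def _polish(rf: RoutingFunction, points: np.ndarray, iters: int = 80) -> np.ndarray:
    """Batch Newton refinement on the log-gradient system ``grad L = 0``.

    Off the boundary the zeros of ``grad L`` are exactly the critical points
    of the routing function; the log form keeps every evaluation at the scale
    of the individual low-degree factors.  Returns converged points only.
    """
    if points.size == 0:
        return points
    fs = rf._fs
    X = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    alive = np.ones(len(X), dtype=bool)
    converged = np.zeros(len(X), dtype=bool)
    for _ in range(iters):
        if not alive.any():
            break
        Xa = X[alive]
        phi, HL = fs.log_hessian_jacobian(Xa)
        with np.errstate(all="ignore"):
            try:
                step = np.linalg.solve(HL, phi[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = np.array(
                    [
                        np.linalg.lstsq(Hi, gi, rcond=None)[0]
                        for Hi, gi in zip(HL, phi)
                    ]
                )
        bad = ~np.isfinite(step).all(axis=1)
        step[bad] = 0.0
        # damp very large steps so near-boundary starts do not overshoot
        norms = np.linalg.norm(step, axis=1)
        scale = 1 + np.linalg.norm(Xa, axis=1)
        big = norms > 0.5 * scale
        step[big] *= (0.5 * scale[big] / norms[big])[:, None]
        Xa = Xa - step
        X[alive] = Xa
        done = (np.linalg.norm(step, axis=1) < 1e-13 * scale) & ~bad
        escaped = (np.linalg.norm(Xa, axis=1) > 1e5) | bad
        idx = np.flatnonzero(alive)
        converged[idx[done]] = True
        alive[idx[done | escaped]] = False
    if not converged.any():
        return np.empty((0, X.shape[1]))
    out = X[converged]
    phi = fs.log_gradient(out)
    ok = np.isfinite(phi).all(axis=1) & (
        np.linalg.norm(phi, axis=1) < 1e-7 * (1 + np.linalg.norm(out, axis=1))
    )
    return out[ok]


def _real_roots_exact(poly: sp.Poly) -> list[float]:
    """Real roots of an exact univariate rational polynomial.

    Factors into irreducibles first (a companion-matrix solve on a high-degree
    polynomial with a wide coefficient range can miss roots), then isolates
    real roots per factor with exact interval arithmetic.
    """
    roots: list[float] = []
    _, factors = sp.factor_list(poly.as_expr(), poly.gens[0])
    for base, _mult in factors:
        fac = sp.Poly(base, poly.gens[0])
        if fac.degree() < 1:
            continue
        for (lo, hi), _k in fac.intervals(eps=sp.Rational(1, 10**10)):
            roots.append(float((lo + hi) / 2))
    return roots


def _solve_resultant_2d(rf: RoutingFunction):
    a1, a2 = rf.parameters
    G1, G2 = [sp.Poly(sp.expand(g), a1, a2, domain="QQ") for g in rf.gradient_system]
    res = sp.resultant(G1, G2, a2)
    res = sp.Poly(res, a1) if not isinstance(res, sp.Poly) else res
    if res.is_zero:
        raise GenericityError("resultant of the gradient system vanishes identically")
    candidates = []
    g1_poly = sp.Poly(G1.as_expr(), a2)
    g2_poly = sp.Poly(G2.as_expr(), a2)
    for x1 in _real_roots_exact(res):
        seen_a2 = []
        for poly in (g1_poly, g2_poly):
            coeffs2 = np.trim_zeros(
                np.array([float(c.subs(a1, sp.Float(x1, 20))) for c in poly.all_coeffs()]),
                "f",
            )
            if coeffs2.size < 2:
                continue
            for r2 in np.roots(coeffs2):
                if abs(r2.imag) > 1e-4:
                    continue
                x2 = float(r2.real)
                if any(abs(x2 - s) < 1e-10 * (1 + abs(s)) for s in seen_a2):
                    continue
                seen_a2.append(x2)
                candidates.append([x1, x2])
    if not candidates:
        return np.empty((0, 2))
    polished = _polish(rf, np.array(candidates))
    return _dedupe(polished)


def _solve_univariate(rf: RoutingFunction):
    (a1,) = rf.parameters
    G = sp.Poly(sp.expand(rf.gradient_system[0]), a1, domain="QQ")
    coeffs = np.array([float(c) for c in G.all_coeffs()])
    roots = np.roots(coeffs)
    pts = np.array([[float(r.real)] for r in roots if abs(r.imag) < 1e-8])
    return _dedupe(_polish(rf, pts)) if pts.size else np.empty((0, 1))


def _solve_multistart(rf: RoutingFunction, box, seed, n_starts):
    """Newton from several scrambled low-discrepancy batches plus a uniform
    batch; the union makes the found set robust to any single unlucky draw."""
    m = int(np.ceil(np.log2(max(n_starts, 2))))
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    batches = []
    for offset in (0, 1_000_003):
        sampler = qmc.Sobol(d=rf.k, scramble=True, seed=seed + offset)
        batches.append(sampler.random_base2(m))
    rng = np.random.default_rng(seed + 2_000_003)
    batches.append(rng.random((n_starts // 2, rf.k)))
    starts = lo + np.concatenate(batches) * (hi - lo)
    polished = _polish(rf, starts)
    return _dedupe(polished)


def critical_points(
    rf: RoutingFunction,
    method: str = "auto",
    box=None,
    seed: int | None = None,
    n_starts: int | None = None,
    positivity_tol: float = 1e-8,
) -> list[RoutingPoint]:
    """All real critical points of ``rf`` off the boundary, classified.

    Solves the cleared-denominator gradient system, deduplicates, excludes
    points where the numerator vanishes (on the arrangement or a coordinate
    hyperplane), filters to all-positive coordinates in positive-orthant
    mode, and attaches the Hessian classification to every survivor.
    """
    if method == "auto":
        degree = sp.total_degree(sp.expand(rf.numerator), *rf.parameters)
        if rf.k == 1:
            method = "resultant"
        elif rf.k == 2 and degree <= 12:
            method = "resultant"
        else:
            method = "multistart"
    if seed is None:
        seed = (rf.seed or 0) + 1

    if method == "resultant":
        if rf.k == 1:
            raw = _solve_univariate(rf)
        elif rf.k == 2:
            raw = _solve_resultant_2d(rf)
        else:
            raise ValueError("resultant solver supports k <= 2")
    elif method == "multistart":
        if box is None:
            span = max(10.0, 2.5 * max(float(c) for c in rf.center))
            box = [(positivity_tol, span)] * rf.k
        if n_starts is None:
            n_starts = 2**13 if rf.k <= 2 else 2**14
        raw = _solve_multistart(rf, box, seed, n_starts)
    else:
        raise ValueError(f"unknown solver method {method!r}")

    points: list[RoutingPoint] = []
    for coords in np.atleast_2d(raw) if raw.size else []:
        if rf.restrict_positive and np.any(coords <= positivity_tol):
            continue
        if rf.on_boundary(coords):
            continue
        points.append(classify(rf, coords))
    points.sort(key=lambda p: tuple(np.round(p.coords, 9)))
    return points


def classify(rf: RoutingFunction, point) -> RoutingPoint:
    """Complete a critical point: Hessian spectrum, index, unstable directions.

    The index counts Hessian eigenvalues sharing the sign of the value.  The
    computation uses the scaled Hessian ``M = H / r = grad L grad L^T + HL``
    (with ``L = log|r|``), whose positive eigenvalues correspond exactly to
    Hessian eigenvalues of ``r``'s sign, so high-degree numerators never
    overflow.  An eigenvalue within the degeneracy tolerance of zero violates
    genericity and raises :class:`GenericityError`.
    """
    coords = np.asarray(point, dtype=float)
    fs = rf._fs
    phi, HL = fs.log_hessian_jacobian(coords[None, :])
    phi, HL = phi[0], HL[0]
    residual = float(np.linalg.norm(phi))
    if residual > 1e-6 * (1 + np.linalg.norm(coords)):
        raise ValueError(f"point {coords} is not critical (|grad log r| = {residual:.2e})")
    M = np.outer(phi, phi) + HL
    eigvals, eigvecs = np.linalg.eigh((M + M.T) / 2)
    radius = float(np.max(np.abs(eigvals)))
    if radius == 0 or np.min(np.abs(eigvals)) < DEGENERACY_TOL * radius:
        raise GenericityError(
            f"degenerate Hessian at {coords}: scaled eigenvalues {eigvals}"
        )
    unstable_mask = eigvals > 0
    directions = []
    for i in np.flatnonzero(unstable_mask):
        v = eigvecs[:, i] / np.linalg.norm(eigvecs[:, i])
        directions.extend([v, -v])
    with np.errstate(all="ignore"):
        value = rf.value(coords)
    return RoutingPoint(
        coords=coords,
        value=value,
        sign=rf.sign_value(coords),
        log_abs=rf.log_abs(coords),
        gradient_residual=residual,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        index=int(np.count_nonzero(unstable_mask)),
        unstable_directions=directions,
    )


@dataclass
class GenericityReport:
    """Outcome of the genericity checks for a classified point set."""

    passed: bool
    reasons: list[str] = field(default_factory=list)


def genericity_check(rf: RoutingFunction, points) -> GenericityReport:
    """Check the genericity conditions on a classified routing point set.

    Verifies pairwise distinctness of the nonzero critical values and
    nondegeneracy of every Hessian; an empty point list passes vacuously.
    Failure means the center ``c`` should be re-drawn.
    """
    reasons = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            a, b = points[i], points[j]
            if a.sign != b.sign:
                continue
            scale = max(abs(a.log_abs), abs(b.log_abs), 1.0)
            if abs(a.log_abs - b.log_abs) <= VALUE_TIE_TOL * scale:
                reasons.append(
                    f"critical values at {a.coords} and {b.coords} coincide"
                    f" (log|r| = {a.log_abs:.12e}, {b.log_abs:.12e})"
                )
    for p in points:
        if p.index is None:
            reasons.append(f"point {p.coords} is unclassified")
        radius = float(np.max(np.abs(p.eigenvalues))) if p.eigenvalues.size else 0.0
        if radius == 0 or np.min(np.abs(p.eigenvalues)) < DEGENERACY_TOL * radius:
            reasons.append(f"degenerate Hessian at {p.coords}")
    return GenericityReport(passed=not reasons, reasons=reasons)


def routing_points(
    arr: HypersurfaceArrangement,
    seed: int = 0,
    restrict_positive: bool = True,
    max_redraws: int = 5,
    **solver_kwargs,
):
    """Build a routing function and compute its classified routing points,
    re-drawing the center (up to ``max_redraws`` seeds, each logged) whenever
    a genericity condition fails.

    Returns ``(rf, points, report)``.
    """
    failures = []
    for attempt in range(max_redraws):
        attempt_seed = seed + attempt
        rf = build_routing_function(
            arr, seed=attempt_seed, restrict_positive=restrict_positive
        )
        try:
            points = critical_points(rf, **solver_kwargs)
        except GenericityError as exc:
            failures.append(f"seed {attempt_seed}: {exc}")
            logger.info("genericity failure with seed %s; re-drawing c", attempt_seed)
            continue
        report = genericity_check(rf, points)
        if report.passed:
            return rf, points, report
        failures.append(f"seed {attempt_seed}: {'; '.join(report.reasons)}")
        logger.info("genericity failure with seed %s; re-drawing c", attempt_seed)
    raise GenericityError(
        "no generic center found after {} attempts: {}".format(
            max_redraws, " | ".join(failures)
        )
    )
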