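"""Independent brute-force oracle for connected components of arrangement
complements (sign-vector flood fill on a grid), plus a seeded random
arrangement generator for property tests.

The grid count is a lower-bound estimate of the number of regions: a region
thinner than a cell can be missed, and a pinched region can be fused.  It is
therefore only reported once it is stable under one resolution doubling; the
routing graph is the primary method and the grid its cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sparse
import scipy.sparse.csgraph as csgraph
import sympy as sp

from .boundaries import HypersurfaceArrangement, canonical_factor, _factor_key

__all__ = ["GridLabeling", "grid_components", "random_arrangement"]


@dataclass
class GridLabeling:
    """Flood-fill labeling of an axis-aligned box by arrangement sign vectors.

    Cells are joined only when axis-adjacent with identical sign vectors over
    all arrangement polynomials.  ``representatives`` holds one interior point
    per component, never taken from a cell adjacent to a sign change.
    """

    box: tuple[tuple[float, float], ...]
    resolution: tuple[int, ...]
    labels: np.ndarray  # flat component label per cell
    n_components: int
    representatives: list[tuple[float, ...]]
    stabilized: bool = True
    inconclusive: bool = False

    @property
    def shape(self) -> tuple[int, ...]:
        return self.resolution

    def cell_of(self, point) -> tuple[int, ...]:
        idx = []
        for (lo, hi), res, coord in zip(self.box, self.resolution, point):
            i = int(np.floor((coord - lo) / (hi - lo) * res))
            idx.append(min(max(i, 0), res - 1))
        return tuple(idx)

    def label_at(self, point) -> int:
        flat = np.ravel_multi_index(self.cell_of(point), self.resolution)
        return int(self.labels[flat])


def _poly_functions(arr, parameters=None):
    if isinstance(arr, HypersurfaceArrangement):
        params = arr.parameters
        polys = arr.polynomials
    else:
        params = tuple(parameters)
        polys = list(arr)
    funcs = [sp.lambdify(params, p, "numpy") for p in polys]
    return funcs, len(params)


def _label_once(funcs, k, box, resolution, chunk_size: int = 2_000_000):
    res = tuple(int(resolution) for _ in range(k)) if np.isscalar(resolution) else tuple(resolution)
    axes = [
        lo + (np.arange(r) + 0.5) * (hi - lo) / r
        for (lo, hi), r in zip(box, res)
    ]
    n = int(np.prod(res))

    code = np.empty(n, dtype=np.int64)
    margin = np.empty(n, dtype=np.float32)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        idx = np.unravel_index(np.arange(start, stop), res)
        coords = [axes[d][idx[d]] for d in range(k)]
        c = np.zeros(stop - start, dtype=np.int64)
        m = np.full(stop - start, np.inf, dtype=np.float32)
        for bit, f in enumerate(funcs):
            vals = np.asarray(f(*coords), dtype=float)
            if vals.shape != (stop - start,):
                vals = np.broadcast_to(vals, (stop - start,)).copy()
            c |= (vals > 0).astype(np.int64) << bit
            np.minimum(m, np.abs(vals, dtype=np.float32, casting="unsafe"), out=m)
        code[start:stop] = c
        margin[start:stop] = m

    # guard cells are adjacent to a sign change; they rasterize the boundary
    # layer and are excluded from counting (they would otherwise fragment
    # regions thinner than a cell into spurious components)
    code_nd = code.reshape(res)
    guard = np.zeros(res, dtype=bool)
    for axis in range(k):
        sl_a = [slice(None)] * k
        sl_b = [slice(None)] * k
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        diff = code_nd[tuple(sl_a)] != code_nd[tuple(sl_b)]
        guard[tuple(sl_a)] |= diff
        guard[tuple(sl_b)] |= diff

    # adjacency between interior (non-guard) cells with equal sign vectors;
    # diagonal (Chebyshev) neighbors are included because thin chamber sheets
    # tilted against the axes would otherwise lose face-connectivity.  The
    # guard layer prevents false diagonal merges across transversal crossings.
    flat_index = np.arange(n, dtype=np.int64).reshape(res)
    interior_nd = ~guard
    rows, cols = [], []
    offsets = [
        off
        for off in np.ndindex(*(3,) * k)
        if any(o != 1 for o in off)
    ]
    for off in offsets:
        delta = tuple(o - 1 for o in off)
        first = next(d for d in delta if d != 0)
        if first < 0:
            continue  # keep one orientation per offset pair
        sl_a, sl_b = [], []
        for d in delta:
            if d == 1:
                sl_a.append(slice(None, -1))
                sl_b.append(slice(1, None))
            elif d == -1:
                sl_a.append(slice(1, None))
                sl_b.append(slice(None, -1))
            else:
                sl_a.append(slice(None))
                sl_b.append(slice(None))
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)
        ok = (
            interior_nd[sl_a]
            & interior_nd[sl_b]
            & (code_nd[sl_a] == code_nd[sl_b])
        )
        rows.append(flat_index[sl_a][ok].reshape(-1).astype(np.int64))
        cols.append(flat_index[sl_b][ok].reshape(-1).astype(np.int64))
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    graph = sparse.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    _, raw_labels = csgraph.connected_components(graph, directed=False)

    interior = ~guard.reshape(-1)
    interior_labels = np.unique(raw_labels[interior])
    remap = np.full(raw_labels.max() + 1, -1, dtype=np.int64)
    remap[interior_labels] = np.arange(interior_labels.size)
    labels = np.where(interior, remap[raw_labels], -1)
    n_comp = int(interior_labels.size)

    margin_rep = np.where(interior, margin, -np.inf)
    order = np.lexsort((-margin_rep, labels))
    order = order[labels[order] >= 0]
    sorted_labels = labels[order]
    first = np.searchsorted(sorted_labels, np.arange(n_comp), side="left")
    reps = []
    unravel = np.unravel_index(order[first], res)
    for comp in range(n_comp):
        cell = tuple(int(u[comp]) for u in unravel)
        reps.append(tuple(float(axes[d][cell[d]]) for d in range(k)))
    return GridLabeling(
        box=tuple(tuple(map(float, b)) for b in box),
        resolution=res,
        labels=labels,
        n_components=n_comp,
        representatives=reps,
    )


def _sign_code(funcs, point):
    code = 0
    for bit, f in enumerate(funcs):
        val = float(f(*point))
        if val == 0.0:
            return None
        code |= int(val > 0) << bit
    return code


def _witness_path(funcs, p, q, samples: int = 800) -> bool:
    """Whether a sampled constant-sign-vector path connects ``p`` and ``q``.

    Tries the straight segment and radial detours through scaled midpoints
    (which reconnect thin cone chambers pinched near the origin).  A
    successful path is a connectivity witness; failure proves nothing.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    target = _sign_code(funcs, p)
    if target is None or target != _sign_code(funcs, q):
        return False
    mid = p + q
    norm = np.linalg.norm(mid)
    waypoints = [
        [p, q],
        [p, mid, q],
        [p, 2 * mid / norm, q],
        [p, 4 * mid / norm, q],
    ]
    for path in waypoints:
        ok = True
        for a, b in zip(path[:-1], path[1:]):
            ts = np.linspace(0.0, 1.0, samples)[:, None]
            pts = (1 - ts) * a + ts * b
            for bit, f in enumerate(funcs):
                vals = np.asarray(f(*(pts[:, d] for d in range(len(p)))), dtype=float)
                want_positive = bool((target >> bit) & 1)
                if want_positive and not np.all(vals > 0):
                    ok = False
                    break
                if not want_positive and not np.all(vals < 0):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return True
    return False


def _merge_fragments(gl: GridLabeling, funcs) -> GridLabeling:
    """Merge grid components split by erosion: components whose representatives
    share a sign vector are joined when a witness path connects them."""
    n = gl.n_components
    codes = [_sign_code(funcs, rep) for rep in gl.representatives]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if codes[i] is None or codes[i] != codes[j] or find(i) == find(j):
                continue
            if _witness_path(funcs, gl.representatives[i], gl.representatives[j]):
                parent[find(i)] = find(j)

    roots = sorted({find(i) for i in range(n)})
    remap = {root: new for new, root in enumerate(roots)}
    mapping = np.array([remap[find(i)] for i in range(n)], dtype=np.int64)
    labels = np.where(gl.labels >= 0, mapping[np.maximum(gl.labels, 0)], -1)
    reps = [None] * len(roots)
    for i in range(n):
        new = mapping[i]
        if reps[new] is None:
            reps[new] = gl.representatives[i]
    return GridLabeling(
        box=gl.box,
        resolution=gl.resolution,
        labels=labels,
        n_components=len(roots),
        representatives=reps,
        stabilized=gl.stabilized,
        inconclusive=gl.inconclusive,
    )


def grid_components(
    arr,
    box,
    resolution: int = 40,
    parameters=None,
    stabilize: bool = True,
    max_doublings: int = 3,
) -> GridLabeling:
    """Flood-fill component count of the complement of ``arr`` inside ``box``.

    ``arr`` is a :class:`HypersurfaceArrangement` or an iterable of sympy
    polynomials with ``parameters`` given.  Components fragmented by the
    guard-cell erosion are re-joined by sign-vector witness paths.  The count
    must be unchanged under one resolution doubling before it is reported
    (``stabilized``); after ``max_doublings`` unstable doublings the result is
    flagged inconclusive.
    """
    funcs, k = _poly_functions(arr, parameters)
    if k > 4:
        raise ValueError("grid oracle is limited to at most 4 parameters")
    if not funcs:
        empty = _label_once([sp.lambdify(sp.symbols("t0:%d" % k), sp.Integer(1), "numpy")], k, box, resolution)
        empty.stabilized = True
        return empty

    current = _merge_fragments(_label_once(funcs, k, box, resolution), funcs)
    if not stabilize:
        return current
    for _ in range(max_doublings):
        next_res = tuple(2 * r for r in current.resolution)
        if int(np.prod(next_res)) > 20_000_000:
            break  # memory guard: report the finest affordable labeling
        doubled = _merge_fragments(
            _label_once(funcs, k, box, next_res),
            funcs,
        )
        if doubled.n_components == current.n_components:
            doubled.stabilized = True
            return doubled
        current = doubled
    current.stabilized = False
    current.inconclusive = True
    return current


def _pairwise_intersections(polys, params) -> list[tuple[float, float]]:
    """Real pairwise intersection points of 2-D curves.

    Eliminates one variable by a Sylvester resultant per pair (cheap for the
    low-degree lines and conics used here) and recovers the second
    coordinate by univariate root finding.
    """
    a1, a2 = params
    points = []
    funcs = [sp.lambdify(params, p, "numpy") for p in polys]
    scales = [
        float(sum(abs(c) for c in sp.Poly(p, *params).coeffs())) for p in polys
    ]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            res = sp.resultant(sp.Poly(polys[i], a2), sp.Poly(polys[j], a2))
            res = sp.Poly(res, a1) if not isinstance(res, sp.Poly) else res
            if res.is_zero or res.degree() < 1:
                continue
            for r1 in np.roots([float(c) for c in res.all_coeffs()]):
                if abs(r1.imag) > 1e-7:
                    continue
                x1 = float(r1.real)
                uni = sp.Poly(polys[i].subs(a1, sp.Float(x1, 17)), a2)
                coeffs = np.trim_zeros(
                    np.array([float(c) for c in uni.all_coeffs()]), "f"
                )
                if coeffs.size < 2:
                    uni = sp.Poly(polys[j].subs(a1, sp.Float(x1, 17)), a2)
                    coeffs = np.trim_zeros(
                        np.array([float(c) for c in uni.all_coeffs()]), "f"
                    )
                    if coeffs.size < 2:
                        continue
                for r2 in np.roots(coeffs):
                    if abs(r2.imag) > 1e-7:
                        continue
                    pt = (x1, float(r2.real))
                    reach = (1 + max(abs(pt[0]), abs(pt[1]))) ** 2
                    if (
                        abs(float(funcs[i](*pt))) < 1e-6 * scales[i] * reach
                        and abs(float(funcs[j](*pt))) < 1e-6 * scales[j] * reach
                    ):
                        points.append(pt)
    return points


def suggest_box(arr: HypersurfaceArrangement, margin: float = 1.5, floor: float = 12.0):
    """A box guaranteed to see every region of the positive-quadrant complement.

    Covers all pairwise real intersections of the arrangement polynomials
    (including with the coordinate axes): beyond them the arrangement is
    topologically radial, so every region reaches into the box.  2-D only.
    """
    params = arr.parameters
    if len(params) != 2:
        raise ValueError("suggest_box supports 2-D arrangements")
    polys = list(arr.polynomials) + [params[0], params[1]]
    pts = _pairwise_intersections(polys, params)
    extent = max((max(abs(x), abs(y)) for x, y in pts), default=0.0)
    hi = max(floor, margin * extent + 2.0)
    return ((0.0, hi), (0.0, hi))


def _curve_samples(poly, params, box, n=80):
    """Points on the zero curve of a bivariate polynomial inside the box."""
    a1, a2 = params
    out = []
    for fixed, free in ((a1, a2), (a2, a1)):
        poly_u = sp.Poly(poly, free)
        coeff_funcs = [sp.lambdify(fixed, c, "numpy") for c in poly_u.all_coeffs()]
        lo, hi = box[0] if fixed is a1 else box[1]
        for t in np.linspace(lo, hi, n):
            coeffs = np.trim_zeros(np.array([f(t) for f in coeff_funcs], dtype=float), "f")
            if coeffs.size < 2:
                continue
            for r in np.roots(coeffs):
                if abs(r.imag) < 1e-9:
                    pt = (t, float(r.real)) if fixed is a1 else (float(r.real), t)
                    if box[0][0] <= pt[0] <= box[0][1] and box[1][0] <= pt[1] <= box[1][1]:
                        out.append(pt)
    return out


def _well_separated(polys, params, box, min_gap=0.15, cross_clearance=0.5) -> bool:
    """Reject arrangements with thin channels between curves.

    Samples each zero curve and requires the normalized distance
    ``|g_j| / |grad g_j|`` to every other curve to exceed ``min_gap`` except
    near genuine crossings; guarantees that the grid oracle resolves every
    region at moderate resolution.
    """
    all_polys = list(polys) + [params[0], params[1]]
    crossings = _pairwise_intersections(all_polys, params)
    funcs = [sp.lambdify(params, p, "numpy") for p in all_polys]
    grads = [
        [sp.lambdify(params, sp.diff(p, v), "numpy") for v in params]
        for p in all_polys
    ]
    for i, poly in enumerate(polys):
        for pt in _curve_samples(poly, params, box):
            near_cross = any(
                (pt[0] - cx) ** 2 + (pt[1] - cy) ** 2 < cross_clearance**2
                for cx, cy in crossings
            )
            if near_cross:
                continue
            for j in range(len(all_polys)):
                if all_polys[j] == poly:
                    continue
                val = abs(float(funcs[j](*pt)))
                grad = np.array([g(*pt) for g in grads[j]], dtype=float)
                dist = val / (np.linalg.norm(grad) + 1e-12)
                if dist < min_gap:
                    return False
    return True


def random_arrangement(
    k: int,
    m: int,
    degree_menu=(1, 2),
    seed: int = 0,
    box=((1, 9), (1, 9)),
    max_attempts: int = 400,
    well_separated: bool = True,
) -> HypersurfaceArrangement:
    """Random arrangement of lines and conics with rational coefficients.

    Lines pass through two random rational points of the box; conics are
    axis-aligned ellipses centered inside the box, hence nonsingular
    everywhere.  Rejection sampling guarantees pairwise non-associate
    factors and, with ``well_separated``, no thin channels between curves
    and no crossings far outside the box (so a moderate-resolution grid
    resolves every region).  Exhausting the budget raises ``RuntimeError``.
    """
    if k not in (1, 2):
        raise ValueError("random arrangements support k in {1, 2}")
    if m > 4:
        raise ValueError("random arrangements support m <= 4")
    rng = np.random.default_rng(seed)
    params = sp.symbols(f"a1:{k + 1}")
    box = tuple(box)[:k]

    def rational(lo, hi, denom=8):
        return sp.Rational(int(rng.integers(int(lo * denom), int(hi * denom) + 1)), denom)

    def draw():
        degree = int(rng.choice(list(degree_menu)))
        if k == 1:
            return params[0] - rational(*box[0])
        if degree == 1:
            (x0, x1), (y0, y1) = box
            p1 = (rational(x0, x1), rational(y0, y1))
            p2 = (rational(x0, x1), rational(y0, y1))
            if p1 == p2:
                return None
            return (p2[1] - p1[1]) * (params[0] - p1[0]) - (p2[0] - p1[0]) * (
                params[1] - p1[1]
            )
        (x0, x1), (y0, y1) = box
        cx = rational(x0 + (x1 - x0) / 4, x1 - (x1 - x0) / 4)
        cy = rational(y0 + (y1 - y0) / 4, y1 - (y1 - y0) / 4)
        lam1 = rational(1, 4)
        lam2 = rational(1, 4)
        radius = rational((x1 - x0) / 8, (x1 - x0) / 3)
        return lam1 * (params[0] - cx) ** 2 + lam2 * (params[1] - cy) ** 2 - radius**2

    attempts = 0
    while True:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("rejection budget exhausted while sampling arrangement")
        polys, keys = [], set()
        budget = 20 * (m + 1)
        while len(polys) < m and budget:
            budget -= 1
            cand = draw()
            if cand is None:
                continue
            cand = canonical_factor(cand, params)
            key = _factor_key(cand, params)
            if key in keys:
                continue
            keys.add(key)
            polys.append(cand)
        if len(polys) < m:
            continue
        if k == 2 and m > 0 and well_separated:
            check_box = tuple((lo - 2, hi + 4) for lo, hi in box)
            pts = _pairwise_intersections(list(polys) + [params[0], params[1]], params)
            if any(max(abs(x), abs(y)) > box[0][1] + 6 for x, y in pts):
                continue  # far crossings create far thin wedges
            # clustered crossings (near-tangency, near-triple points) create
            # regions below any reasonable grid resolution
            if any(
                0 < (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < 0.5**2
                for ii, p in enumerate(pts)
                for q in pts[ii + 1 :]
            ):
                continue
            if not _well_separated(polys, params, check_box):
                continue
        arr = HypersurfaceArrangement.from_polynomials(params, polys)
        return arr
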