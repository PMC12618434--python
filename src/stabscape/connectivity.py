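"""Gradient-flow connectivity: connect routing points along unstable
directions, build the routing graph, and answer region-membership queries.

From every routing point of index > 0 and every unstable eigenvector
direction ``+/- v``, the ascent flow ``dy/dt = sign(r_c(a)) * grad r_c(y)``
started at ``a + eps*v`` stays inside one connected component of the
complement and terminates at another routing point of strictly larger
``|r_c|``.  The graph on routing points whose edges are these trajectories
has one connected component per region of the complement, which reduces
region enumeration to graph connectivity.

Numerically the integrated field is ``grad log|r_c|``: since
``sign(r) grad r = |r| grad log|r|`` and ``|r| > 0`` off the boundary, the
trajectories are identical up to time rescaling, while the log form stays
finite for numerators of arbitrarily high degree and repels trajectories
from the boundary (where ``log|r| -> -inf``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp

from .routing import RoutingFunction, RoutingPoint, _polish

__all__ = [
    "RoutingGraph",
    "TraceError",
    "trace_unstable_path",
    "build_routing_graph",
    "connected_components",
    "locate",
]

#: Launch offset along an unstable direction, scaled by the point norm.
LAUNCH_EPS = 1e-4
#: Escape bound: trajectories beyond this norm are integration failures.
ESCAPE_NORM = 1e6
#: Relative landing tolerance for matching a trajectory end to a vertex.
MATCH_TOL = 1e-5


class TraceError(RuntimeError):
    """A gradient-flow trajectory failed to land at a routing point."""


@dataclass
class _Landing:
    vertex: int
    point: RoutingPoint
    path_log_values: list[float]


def _nearest_vertex(y, vertices: list[RoutingPoint]):
    dists = [float(np.linalg.norm(y - v.coords)) for v in vertices]
    order = np.argsort(dists)
    return int(order[0]), dists[int(order[0])], (
        dists[int(order[1])] if len(order) > 1 else np.inf
    )


def _flow_to_vertex(
    rf: RoutingFunction,
    y0: np.ndarray,
    vertices: list[RoutingPoint],
    rtol: float = 1e-9,
    max_chunks: int = 60,
    label: str = "",
    exclude_vertex: int | None = None,
    min_log_value: float | None = None,
) -> _Landing:
    """Integrate the ascent flow until it lands at a known vertex.

    ``log|r_c|`` must be nondecreasing along the trajectory (ascent toward
    extrema of the matching sign); this is checked at every accepted chunk.
    """
    def rhs(_t, y):
        return rf.log_gradient(y)

    y = np.asarray(y0, dtype=float)
    log_values = [rf.log_abs(y)]
    chunk = 0.01
    for _ in range(max_chunks):
        sol = solve_ivp(rhs, (0.0, chunk), y, method="LSODA", rtol=rtol, atol=1e-12)
        if not sol.success or not np.isfinite(sol.y[:, -1]).all():
            raise TraceError(f"integrator failed while tracing from {label or y0}")
        y = sol.y[:, -1]
        if float(np.linalg.norm(y)) > ESCAPE_NORM:
            raise TraceError(f"trajectory escaped (|y| > {ESCAPE_NORM:g}) from {label or y0}")
        logr = rf.log_abs(y)
        if logr < log_values[-1] - 1e-7 * (1 + abs(log_values[-1])):
            raise TraceError(
                f"|r_c| decreased along the trajectory from {label or y0}"
            )
        log_values.append(logr)
        phi_norm = float(np.linalg.norm(rf.log_gradient(y)))
        may_snap = min_log_value is None or logr > min_log_value + 1e-10 * (1 + abs(min_log_value))
        if phi_norm < 1e-3 * (1 + np.linalg.norm(y)) and may_snap:
            polished = _polish(rf, y[None, :])
            if polished.size:
                y_star = polished[0]
                if np.linalg.norm(y_star - y) < 0.05 * (1 + np.linalg.norm(y)):
                    idx, dist, second = _nearest_vertex(y_star, vertices)
                    scale = 1 + np.linalg.norm(y_star)
                    if dist < MATCH_TOL * scale and idx != exclude_vertex:
                        if second < 2 * max(dist, 1e-12):
                            raise TraceError(
                                f"ambiguous landing near vertices (d1={dist:.2e}, d2={second:.2e});"
                                " re-run with tighter integrator tolerances"
                            )
                        log_values.append(vertices[idx].log_abs)
                        return _Landing(idx, vertices[idx], log_values)
        chunk = min(chunk * 2.0, 1e9)
    raise TraceError(f"trajectory from {label or y0} did not land within {max_chunks} chunks")


def trace_unstable_path(
    rf: RoutingFunction,
    point: RoutingPoint,
    direction: np.ndarray,
    vertices: list[RoutingPoint] | None = None,
    start_index: int | None = None,
) -> RoutingPoint:
    """Follow the ascent flow from a saddle along one unstable direction.

    Starts at ``point + eps * direction`` (with ``eps`` halved and retried if
    the first offset decreases ``|r_c|``) and integrates until the flow lands
    at a routing point, which is returned.  The landing point lies in the
    same connected component and has strictly larger ``|r_c|``.
    """
    if not point.index:
        raise ValueError("only points of index > 0 launch unstable paths")
    if vertices is None:
        raise ValueError("trace_unstable_path needs the candidate landing vertices")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    base_log = point.log_abs
    eps = LAUNCH_EPS * (float(np.linalg.norm(point.coords)) + 1)
    y0 = None
    for _ in range(8):
        candidate = point.coords + eps * direction
        if rf.log_abs(candidate) > base_log:
            y0 = candidate
            break
        eps /= 2
    if y0 is None:
        raise TraceError(f"could not launch an ascending step from {point.coords}")
    if start_index is None:
        dists = [float(np.linalg.norm(point.coords - v.coords)) for v in vertices]
        start_index = int(np.argmin(dists)) if dists and min(dists) < 1e-9 else None
    landing = _flow_to_vertex(
        rf, y0, vertices, label=str(point.coords),
        exclude_vertex=start_index, min_log_value=base_log,
    )
    if landing.point.log_abs <= base_log:
        raise TraceError(
            f"landing at {landing.point.coords} does not increase |r_c| from {point.coords}"
        )
    return landing.point


@dataclass
class RoutingGraph:
    """Routing points with gradient-flow edges and their component partition.

    Every index > 0 vertex contributes two traced paths per unstable
    eigenvector (the ``+v`` and ``-v`` directions); every traced path
    terminates at a vertex.  The components partition the vertex set and are
    in one-to-one correspondence with the regions of the complement; each
    component representative is its index-0 vertex of largest ``|r_c|``.
    """

    vertices: list[RoutingPoint]
    edges: list[tuple[int, int, np.ndarray]] = field(default_factory=list)
    components: list[list[int]] = field(default_factory=list)
    representatives: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_of(self, vertex: int) -> int:
        for cid, members in enumerate(self.components):
            if vertex in members:
                return cid
        raise KeyError(vertex)

    def to_dict(self) -> dict:
        return {
            "vertices": [
                {
                    "coords": [float(x) for x in v.coords],
                    "value": float(v.value),
                    "sign": float(v.sign),
                    "log_abs": float(v.log_abs),
                    "index": v.index,
                    "eigenvalues": [float(x) for x in v.eigenvalues],
                }
                for v in self.vertices
            ],
            "edges": [[int(i), int(j)] for i, j, _ in self.edges],
            "components": [list(map(int, c)) for c in self.components],
            "representatives": list(map(int, self.representatives)),
        }

    def to_dot(self) -> str:
        lines = ["graph routing {"]
        for i, v in enumerate(self.vertices):
            shape = "ellipse" if v.index == 0 else "diamond"
            lines.append(f'  v{i} [label="{i} (idx {v.index})", shape={shape}];')
        for i, j, _ in self.edges:
            lines.append(f"  v{i} -- v{j};")
        lines.append("}")
        return "\n".join(lines)


def build_routing_graph(rf: RoutingFunction, points: list[RoutingPoint]) -> RoutingGraph:
    """Loop over all routing points and all unstable eigenvector directions,
    trace each flow, and assemble the routing graph with its components."""
    G = nx.Graph()
    G.add_nodes_from(range(len(points)))
    edges = []
    for i, p in enumerate(points):
        for direction in p.unstable_directions:
            landing = trace_unstable_path(rf, p, direction, vertices=points, start_index=i)
            j = next(k for k, q in enumerate(points) if q is landing)
            G.add_edge(i, j)
            edges.append((i, j, direction))
    components = [sorted(c) for c in nx.connected_components(G)]
    components.sort(key=lambda c: c[0])
    graph = RoutingGraph(vertices=points, edges=edges, components=components)
    graph.representatives = _representatives(graph)
    return graph


def _representatives(graph: RoutingGraph) -> list[int]:
    reps = []
    for members in graph.components:
        extrema = [i for i in members if graph.vertices[i].index == 0]
        if not extrema:
            raise RuntimeError(
                f"component {members} has no index-0 vertex; routing-point set is incomplete"
            )
        reps.append(max(extrema, key=lambda i: graph.vertices[i].log_abs))
    return reps


def connected_components(graph: RoutingGraph) -> list[dict]:
    """The component partition with per-component representatives."""
    return [
        {
            "component": cid,
            "members": members,
            "representative": graph.representatives[cid],
            "representative_point": graph.vertices[graph.representatives[cid]],
        }
        for cid, members in enumerate(graph.components)
    ]


def locate(
    rf: RoutingFunction,
    graph: RoutingGraph,
    a,
    boundary_tol: float = 1e-8,
) -> int:
    """Component id of the region containing the parameter point ``a``.

    Follows the ascent flow from ``a`` to a routing point and returns that
    point's component.  Points on or numerically near the boundary are
    rejected with a distance diagnostic.
    """
    a = np.asarray(a, dtype=float)
    if rf.on_boundary(a, tol=boundary_tol):
        raise ValueError(
            f"point {a} lies on or near the boundary (log|num/den^D| = {rf.log_abs(a):.3e})"
        )
    idx, dist, _ = _nearest_vertex(a, graph.vertices)
    if dist < MATCH_TOL * (1 + np.linalg.norm(a)):
        return graph.component_of(idx)
    landing = _flow_to_vertex(rf, a, graph.vertices, label=str(a))
    return graph.component_of(landing.vertex)
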