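"""Shared fixtures: built-in models, and the heavier pipeline objects
(two-ellipse routing graph, Levins-Culver boundary/routing/grid) computed
once per session."""

import warnings

import pytest
import sympy as sp

from stabscape import fixtures as fixture_registry
from stabscape.boundaries import decompose_equilibrium_ideal, total_boundary
from stabscape.connectivity import build_routing_graph
from stabscape.oracle import grid_components
from stabscape.routing import build_routing_function, critical_points, routing_points


@pytest.fixture(scope="session")
def registry():
    return fixture_registry()


@pytest.fixture(scope="session")
def two_ellipse_pipeline(registry):
    """Routing function, points and graph for the two-ellipse worked example."""
    arr = registry["two_ellipses"]
    rf = build_routing_function(arr, c=(sp.Rational(6, 5), sp.Rational(7, 10)))
    points = critical_points(rf)
    graph = build_routing_graph(rf, points)
    return rf, points, graph


@pytest.fixture(scope="session")
def lc_system(registry):
    return registry["levins_culver"]


@pytest.fixture(scope="session")
def lc_components(lc_system):
    return decompose_equilibrium_ideal(lc_system)


@pytest.fixture(scope="session")
def lc_arrangement(lc_system, lc_components):
    return total_boundary(lc_system, components=lc_components)


@pytest.fixture(scope="session")
def lc_pipeline(lc_arrangement):
    """The 4-parameter Levins-Culver routing graph (positive orthant)."""
    rf, points, report = routing_points(
        lc_arrangement, seed=0, box=[(1e-6, 8.0)] * 4, n_starts=2**14
    )
    graph = build_routing_graph(rf, points)
    return rf, points, graph


@pytest.fixture(scope="session")
def lc_grid(lc_arrangement):
    """Independent 4-D flood-fill labeling of the Levins-Culver arrangement."""
    return grid_components(lc_arrangement, box=[(0, 3)] * 4, resolution=20, max_doublings=2)


@pytest.fixture(scope="session")
def coral_components(registry):
    return decompose_equilibrium_ideal(registry["coral_reduced"])


@pytest.fixture(autouse=True)
def _quiet_near_boundary():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*near a boundary.*")
        warnings.filterwarnings("ignore", message=".*vanishes identically.*")
        yield
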