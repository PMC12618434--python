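"""Routing functions: degree bookkeeping, critical-point solving,
Hessian classification, and genericity checks."""

import numpy as np
import pytest
import sympy as sp

from stabscape.boundaries import HypersurfaceArrangement
from stabscape.routing import (
    GenericityError,
    build_routing_function,
    classify,
    critical_points,
    genericity_check,
    routing_points,
)


def _single_hyperplane():
    a1 = sp.Symbol("a1")
    return HypersurfaceArrangement.from_polynomials((a1,), [a1 - 1])


class TestBuildRoutingFunction:
    def test_two_ellipse_degrees(self, registry):
        rf = build_routing_function(registry["two_ellipses"], c=(1.2, 0.7))
        assert sp.total_degree(sp.expand(rf.numerator), *rf.parameters) == 6
        assert rf.D == 4  # denominator degree 8
        assert rf.center == (sp.Rational(6, 5), sp.Rational(7, 10))

    def test_levins_culver_exponent_eight(self, lc_arrangement):
        rf = build_routing_function(lc_arrangement, seed=0)
        assert sum(sp.total_degree(f, *rf.parameters) for f in rf.numerator_factors) == 14
        assert rf.D == 8

    def test_single_hyperplane_minimal_exponent(self):
        rf = build_routing_function(_single_hyperplane(), seed=0)
        assert sp.expand(rf.numerator - rf.parameters[0] * (rf.parameters[0] - 1)) == 0
        assert rf.D == 2

    def test_coordinate_factors_not_duplicated(self, lc_arrangement):
        rf = build_routing_function(lc_arrangement, seed=0)
        # the arrangement already contains the four coordinate hyperplanes
        assert len(rf.numerator_factors) == 11


class TestCriticalPoints:
    def test_two_ellipse_nine_points(self, two_ellipse_pipeline):
        rf, points, _ = two_ellipse_pipeline
        assert len(points) == 9

    def test_resultant_and_multistart_agree(self, registry):
        rf = build_routing_function(registry["two_ellipses"], c=(1.2, 0.7))
        exact = critical_points(rf, method="resultant")
        multi = critical_points(rf, method="multistart", box=[(1e-6, 18)] * 2,
                                n_starts=2**13, seed=5)
        exact_set = sorted(tuple(np.round(p.coords, 6)) for p in exact)
        multi_set = sorted(tuple(np.round(p.coords, 6)) for p in multi)
        assert exact_set == multi_set

    def test_single_hyperplane_one_point_per_interval(self):
        rf = build_routing_function(_single_hyperplane(), seed=0)
        points = critical_points(rf)
        assert len(points) == 2
        inside = [p for p in points if 0 < p.coords[0] < 1]
        outside = [p for p in points if p.coords[0] > 1]
        assert len(inside) == 1 and len(outside) == 1
        assert inside[0].sign * outside[0].sign < 0

    def test_single_hyperplane_matches_dense_scan(self):
        """1-D oracle: sign changes of d(r)/da on a dense grid."""
        rf = build_routing_function(_single_hyperplane(), seed=0)
        xs = np.linspace(1e-4, 30, 300001)
        vals = np.array([rf._fs.value(np.array([[x]]))[0] for x in xs[:: 100]])
        # derivative sign changes away from the boundary zeros
        grads = np.gradient(vals, xs[::100])
        interior = (np.abs(xs[::100] - 1) > 1e-2) & (xs[::100] > 1e-2)
        flips = np.sum(np.diff(np.sign(grads[interior])) != 0)
        assert flips == len(critical_points(rf))

    def test_circle_matches_grid_extremum_scan(self):
        a1, a2 = sp.symbols("a1 a2")
        arr = HypersurfaceArrangement.from_polynomials(
            (a1, a2), [(a1 - 3) ** 2 + (a2 - 3) ** 2 - 1]
        )
        rf = build_routing_function(arr, c=(1.1, 0.9))
        points = critical_points(rf)
        # independent oracle: strict local extrema of r on a 400x400 grid
        xs = np.linspace(0.01, 8, 400)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        P = np.column_stack([X.ravel(), Y.ravel()])
        V = rf._fs.value(P).reshape(400, 400)
        core = V[1:-1, 1:-1]
        neighbors = [V[2:, 1:-1], V[:-2, 1:-1], V[1:-1, 2:], V[1:-1, :-2],
                     V[2:, 2:], V[2:, :-2], V[:-2, 2:], V[:-2, :-2]]
        is_max = np.all([core > n for n in neighbors], axis=0)
        is_min = np.all([core < n for n in neighbors], axis=0)
        n_extrema_grid = int(is_max.sum() + is_min.sum())
        n_extrema = sum(1 for p in points if p.index == 0)
        assert n_extrema == n_extrema_grid
        assert all(0 < p.coords[0] and 0 < p.coords[1] for p in points)


class TestClassify:
    def test_two_ellipse_seven_extrema_two_saddles(self, two_ellipse_pipeline):
        _, points, _ = two_ellipse_pipeline
        assert sum(1 for p in points if p.index == 0) == 7
        assert sum(1 for p in points if p.index == 1) == 2

    def test_global_peak_near_center_is_a_positive_maximum(self, two_ellipse_pipeline):
        rf, points, _ = two_ellipse_pipeline
        peak = max(points, key=lambda p: p.log_abs)
        assert peak.index == 0 and peak.sign > 0
        assert np.linalg.norm(peak.coords - np.array([1.2, 0.7])) < 0.5
        assert not peak.unstable_directions

    def test_index_matches_finite_difference_hessian(self, two_ellipse_pipeline):
        """Independent oracle: central finite differences of r itself."""
        rf, points, _ = two_ellipse_pipeline
        h = 1e-4
        for p in points:
            x0 = p.coords
            H = np.zeros((2, 2))
            for i in range(2):
                for j in range(2):
                    for si in (-1, 1):
                        for sj in (-1, 1):
                            pt = x0.copy()
                            pt[i] += si * h
                            pt[j] += sj * h
                            H[i, j] += si * sj * rf.value(pt)
                    H[i, j] /= 4 * h * h
            eigs = np.linalg.eigvalsh((H + H.T) / 2)
            index_fd = int(np.sum(np.sign(eigs) == p.sign))
            assert index_fd == p.index

    def test_saddles_carry_two_opposite_unstable_directions(self, two_ellipse_pipeline):
        _, points, _ = two_ellipse_pipeline
        for p in points:
            if p.index == 1:
                assert len(p.unstable_directions) == 2
                v, w = p.unstable_directions
                assert np.allclose(v, -w)

    def test_non_critical_point_rejected(self, two_ellipse_pipeline):
        rf, _, _ = two_ellipse_pipeline
        with pytest.raises(ValueError):
            classify(rf, np.array([3.0, 1.0]))


class TestGenericity:
    def test_two_ellipse_center_passes(self, two_ellipse_pipeline):
        rf, points, _ = two_ellipse_pipeline
        assert genericity_check(rf, points).passed

    def test_center_on_symmetry_axis_fails(self):
        a1, a2 = sp.symbols("a1 a2")
        arr = HypersurfaceArrangement.from_polynomials(
            (a1, a2),
            [(a1 - 3) ** 2 + (a2 - 3) ** 2 - 1, (a1 - 7) ** 2 + (a2 - 3) ** 2 - 1],
        )
        # the arrangement (with coordinate factors) is symmetric under
        # a1 -> 10 - a1 only without the a1 factor; drop coordinates to keep
        # the mirror symmetry exact and put c on the axis a1 = 5
        rf = build_routing_function(arr, c=(5, sp.Rational(3, 2)),
                                    restrict_positive=False)
        points = critical_points(rf, method="multistart",
                                 box=[(0.5, 9.5), (0.5, 9.5)], n_starts=2**12, seed=1)
        report = genericity_check(rf, points)
        assert not report.passed
        assert any("coincide" in r for r in report.reasons)

    def test_empty_point_list_passes_vacuously(self, two_ellipse_pipeline):
        rf, _, _ = two_ellipse_pipeline
        assert genericity_check(rf, []).passed

    def test_routing_points_redraws_until_generic(self, registry):
        rf, points, report = routing_points(registry["two_ellipses"], seed=0)
        assert report.passed and len(points) == 9


class TestInvariants:
    def test_seed_invariance_of_critical_point_set(self, registry):
        rf = build_routing_function(registry["two_ellipses"], c=(1.2, 0.7))
        sets = []
        for seed in (11, 22, 33):
            pts = critical_points(rf, method="multistart", box=[(1e-6, 18)] * 2,
                                  n_starts=2**13, seed=seed)
            sets.append(sorted(tuple(np.round(p.coords, 6)) for p in pts))
        assert sets[0] == sets[1] == sets[2]

    def test_vanishing_at_infinity(self, two_ellipse_pipeline):
        rf, points, _ = two_ellipse_pipeline
        smallest = min(p.log_abs for p in points)
        rng = np.random.default_rng(0)
        far = rng.uniform(0, 1, size=(100, 2))
        far = 1e3 * (far + 0.1) / np.linalg.norm(far + 0.1, axis=1, keepdims=True)
        logs = rf._fs.log_abs(far)
        assert np.all(logs < smallest - np.log(10))

    def test_every_region_has_an_index0_point(self, two_ellipse_pipeline, registry):
        from stabscape.oracle import grid_components

        rf, points, _ = two_ellipse_pipeline
        gl = grid_components(registry["two_ellipses"], box=((0, 16), (0, 16)),
                             resolution=300, max_doublings=1, stabilize=False)
        labels = {gl.label_at(p.coords) for p in points if p.index == 0}
        assert len(labels - {-1}) == gl.n_components
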