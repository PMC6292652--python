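import numpy as np
import pytest

from conftest import radial_field, rotational_field, saddle_field
from wavepatt.detection import (
    classify_critical_point,
    detect_critical_points,
    detect_global_intervals,
    find_critical_points,
    jacobian_at,
    order_parameter_R,
    order_parameter_phi,
    pattern_extent,
    ring_path,
    winding_number,
)


def poly_field(roots, conj_roots=(), shape=(16, 16)):
    """u, v = Re/Im of prod (z - r) * prod conj(z - s): index +1 per root,
    -1 per conjugated root (brute-force index-additivity oracle)."""
    rows, cols = shape
    yy, xx = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    z = xx + 1j * yy
    f = np.ones_like(z)
    for r in roots:
        f = f * (z - complex(*r))
    for s in conj_roots:
        f = f * np.conj(z - complex(*s))
    return f.real, f.imag


class TestFindCriticalPoints:
    def test_linear_fields_single_zero(self):
        u, v = radial_field((12, 12), (5.5, 5.5))
        pts = find_critical_points(u, v)
        assert len(pts) == 1
        np.testing.assert_allclose(pts[0], (5.5, 5.5), atol=1e-9)

    def test_uniform_field_empty(self):
        u = np.ones((10, 10))
        pts = find_critical_points(u, u)
        assert pts == []

    def test_quadratic_roots_recovered(self):
        yy, xx = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        u = (xx - 3.0) * (xx - 8.0)
        v = yy - 5.0
        pts = sorted(find_critical_points(u, v))
        assert len(pts) == 2
        np.testing.assert_allclose(pts[0], (3.0, 5.0), atol=0.05)
        np.testing.assert_allclose(pts[1], (8.0, 5.0), atol=0.05)

    def test_subcell_position(self):
        u, v = radial_field((10, 10), (4.3, 6.7))
        pts = find_critical_points(u, v)
        assert len(pts) == 1
        np.testing.assert_allclose(pts[0], (4.3, 6.7), atol=1e-9)

    def test_duplicate_merging(self):
        # a zero exactly on a cell edge is seen by two cells; must merge
        u, v = radial_field((10, 10), (5.0, 5.0))
        pts = find_critical_points(u, v)
        assert len(pts) == 1


class TestJacobian:
    def test_linear_field_exact(self):
        yy, xx = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        J = jacobian_at(2.0 * xx, -1.0 * yy, (4.7, 5.2))
        np.testing.assert_allclose(J, [[2, 0], [0, -1]], atol=1e-12)

    def test_rotation_field(self):
        yy, xx = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        J = jacobian_at(-1.0 * yy, 1.0 * xx, (5.0, 5.0))
        np.testing.assert_allclose(J, [[0, -1], [1, 0]], atol=1e-12)

    def test_quadratic_centered_difference_exact(self):
        yy, xx = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        J = jacobian_at(xx.astype(float) ** 2, np.zeros_like(xx, dtype=float), (2.0, 5.0))
        assert J[0, 0] == pytest.approx(4.0)

    def test_boundary_position_rejected(self):
        u = np.zeros((8, 8))
        with pytest.raises(ValueError):
            jacobian_at(u, u, (0.4, 4.0))


class TestClassify:
    # the printed inequality convention labels tau > 0 as stable; the
    # default ("standard") labels attracting flow (tau < 0) stable, which
    # keeps outward-flowing nodes (sources) unstable
    def test_node_inverted_convention(self):
        J = np.array([[2.0, 0.0], [0.0, 1.0]])  # tau=3, det=2, tau^2=9>8
        assert classify_critical_point(J, "inverted") == "stable_node"
        assert classify_critical_point(J, "standard") == "unstable_node"

    def test_focus_inverted_convention(self):
        J = np.array([[1.0, -2.0], [2.0, 1.0]])  # tau=2, det=5, tau^2=4<20
        assert classify_critical_point(J, "inverted") == "stable_focus"
        assert classify_critical_point(J, "standard") == "unstable_focus"

    def test_saddle(self):
        J = np.array([[1.0, 0.0], [0.0, -1.0]])
        assert classify_critical_point(J) == "saddle"

    def test_degenerate(self):
        assert classify_critical_point(np.zeros((2, 2))) == "degenerate"

    def test_boundary_tie_is_node(self):
        J = np.eye(2)  # tau^2 == 4*det exactly
        assert classify_critical_point(J).endswith("node")

    def test_center_flagged(self):
        J = np.array([[0.0, -1.0], [1.0, 0.0]])  # tau=0, det=1
        assert classify_critical_point(J) == "unstable_focus_center"

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            classify_critical_point(np.eye(2), "bogus")


class TestWindingNumber:
    def test_radial_outflow_plus_one(self):
        u, v = radial_field((12, 12), (5.5, 5.5))
        ring = ring_path((5.5, 5.5), 3, (12, 12))
        assert winding_number(u, v, ring) == 1

    def test_saddle_minus_one(self):
        u, v = saddle_field((12, 12), (5.5, 5.5))
        ring = ring_path((5.5, 5.5), 3, (12, 12))
        assert winding_number(u, v, ring) == -1

    def test_uniform_field_zero(self):
        u = np.ones((12, 12))
        v = np.zeros((12, 12))
        ring = ring_path((5.5, 5.5), 3, (12, 12))
        assert winding_number(u, v, ring) == 0

    def test_focus_plus_one(self):
        u, v = rotational_field((12, 12), (5.5, 5.5))
        ring = ring_path((5.5, 5.5), 2, (12, 12))
        assert winding_number(u, v, ring) == 1

    def test_zero_vector_on_path_errors(self):
        u = np.zeros((6, 6))
        with pytest.raises(ValueError, match="zero-magnitude"):
            winding_number(u, u, [(1, 1), (2, 1), (2, 2), (1, 2)])

    def test_index_additivity_two_sources(self):
        # product of two complex linear factors: index +1 at each root
        u, v = poly_field(roots=[(6.0, 8.0), (10.0, 8.0)])
        ring = ring_path((8.0, 8.0), 5, (16, 16))
        assert winding_number(u, v, ring) == 2

    def test_index_additivity_source_plus_saddle(self):
        u, v = poly_field(roots=[(6.0, 8.0)], conj_roots=[(10.0, 8.0)])
        ring = ring_path((8.0, 8.0), 5, (16, 16))
        assert winding_number(u, v, ring) == 0

    def test_raw_value_close_to_integer(self):
        u, v = radial_field((12, 12), (5.5, 5.5))
        ring = ring_path((5.5, 5.5), 3, (12, 12))
        idx, raw = winding_number(u, v, ring, return_raw=True)
        assert idx == 1
        assert abs(raw - 1.0) < 1e-9


class TestPatternExtent:
    def _cp(self, u, v, x, y):
        J = jacobian_at(u, v, (x, y))
        cls = classify_critical_point(J)
        from wavepatt.detection import CriticalPoint

        return CriticalPoint(
            x=x, y=y, cls=cls, trace=float(np.trace(J)), det=float(np.linalg.det(J))
        )

    def test_isolated_source_extent_grows_to_boundary(self):
        u, v = radial_field((12, 12), (5.5, 5.5))
        cp = self._cp(u, v, 5.5, 5.5)
        # rings r=1..5 all consistent; r=6 would touch the boundary
        assert pattern_extent(u, v, cp) == 5

    def test_saddle_consistent_everywhere(self):
        u, v = saddle_field((12, 12), (5.5, 5.5))
        cp = self._cp(u, v, 5.5, 5.5)
        assert pattern_extent(u, v, cp) == 5

    def test_two_sources_limit_each_others_extent(self):
        u, v = poly_field(roots=[(6.5, 8.0), (9.5, 8.0)])
        cp = self._cp(u, v, 6.5, 8.0)
        ext = pattern_extent(u, v, cp)
        # growth must stop once a ring encloses the second zero (index +2);
        # the centres are 3 apart, so the extent cannot exceed 3
        assert 1 <= ext <= 3

    def test_off_center_terminates_at_nearest_edge(self):
        u, v = radial_field((12, 12), (2.5, 5.5))
        cp = self._cp(u, v, 2.5, 5.5)
        assert pattern_extent(u, v, cp) == 2


class TestDetectCriticalPoints:
    def test_edge_margin_discards(self):
        u, v = radial_field((12, 12), (1.0, 5.5))
        assert detect_critical_points(u, v, edge_margin=2.0) == []

    def test_planted_classes(self):
        for maker, expected in [
            (lambda: radial_field((12, 12), (5.5, 5.5), sign=1.0), "unstable_node"),
            (lambda: radial_field((12, 12), (5.5, 5.5), sign=-1.0), "stable_node"),
            (lambda: saddle_field((12, 12), (5.5, 5.5)), "saddle"),
        ]:
            u, v = maker()
            cps = detect_critical_points(u, v)
            assert len(cps) == 1
            assert cps[0].cls == expected


class TestOrderParameters:
    def test_phi_uniform_is_one(self):
        u = np.ones((10, 10))
        v = np.zeros((10, 10))
        assert order_parameter_phi(u, v) == pytest.approx(1.0, abs=1e-15)

    def test_phi_cancellation_zero(self):
        u = np.ones((10, 10))
        u[:, 5:] = -1.0
        v = np.zeros((10, 10))
        assert order_parameter_phi(u, v) == pytest.approx(0.0, abs=1e-15)

    def test_phi_two_orthogonal_vectors(self):
        u = np.array([[1.0, 0.0]])
        v = np.array([[0.0, 1.0]])
        assert order_parameter_phi(u, v) == pytest.approx(np.sqrt(2) / 2)

    def test_phi_all_zero_errors(self):
        with pytest.raises(ValueError):
            order_parameter_phi(np.zeros((4, 4)), np.zeros((4, 4)))

    def test_phi_rotation_invariant(self, rng):
        u = rng.normal(size=(8, 8))
        v = rng.normal(size=(8, 8))
        phi0 = order_parameter_phi(u, v)
        for ang in rng.uniform(0, 2 * np.pi, size=5):
            u2 = u * np.cos(ang) - v * np.sin(ang)
            v2 = u * np.sin(ang) + v * np.cos(ang)
            assert order_parameter_phi(u2, v2) == pytest.approx(phi0, abs=1e-12)

    def test_R_identical_phases_is_one(self):
        theta = np.full((10, 10), 1.234)
        assert order_parameter_R(theta) == pytest.approx(1.0, abs=1e-15)

    def test_R_roots_of_unity_zero(self):
        n = 16
        theta = 2 * np.pi * np.arange(n) / n
        assert order_parameter_R(theta.reshape(4, 4)) == pytest.approx(0.0, abs=1e-12)

    def test_R_two_phases(self):
        theta = np.array([[0.0, np.pi / 2]])
        assert order_parameter_R(theta) == pytest.approx(np.sqrt(2) / 2)

    def test_R_global_shift_invariant(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=(6, 6))
        R0 = order_parameter_R(theta)
        for shift in rng.uniform(0, 2 * np.pi, size=5):
            assert order_parameter_R(theta + shift) == pytest.approx(R0, abs=1e-12)

    def test_R_is_one_minus_circular_variance(self, rng):
        from scipy.stats import circvar

        theta = rng.uniform(-np.pi, np.pi, size=(8, 8))
        R = order_parameter_R(theta)
        assert R == pytest.approx(1.0 - circvar(theta.ravel()), abs=1e-12)


class TestGlobalIntervals:
    def test_ten_steps_above(self):
        phi = np.full(10, 0.9)
        assert detect_global_intervals(phi, 0.85) == [(0, 9)]

    def test_too_short_discarded(self):
        phi = np.zeros(10)
        phi[2:5] = 0.9  # 3 steps < tdur=5
        assert detect_global_intervals(phi, 0.85) == []

    def test_gap_bridging(self):
        phi = np.zeros(12)
        phi[1:5] = 0.9
        phi[6:10] = 0.9  # 1-step gap, tgap=1 bridges -> length 9
        assert detect_global_intervals(phi, 0.85, tdur=5, tgap=1) == [(1, 9)]

    def test_gap_too_long_not_bridged(self):
        phi = np.zeros(20)
        phi[0:5] = 0.9
        phi[8:13] = 0.9  # 3-step gap > tgap=1
        assert detect_global_intervals(phi, 0.85, tdur=5, tgap=1) == [(0, 4), (8, 12)]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            detect_global_intervals(np.zeros(5), 1.5)
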