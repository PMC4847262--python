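"""Geometry kernel: areas, centroids, plane cuts, chords, slab clipping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lvfusion.errors import (
    EmptyRegionError,
    InvalidGeometryError,
    MissingChordError,
    NoIntersectionError,
)
from lvfusion.geometry import (
    ImagePlane,
    LineSegment3,
    PlanarContour,
    angle_plane_to_line,
    chord_through,
    clip_contour_between_planes,
    plane_contour_intersection,
    polygon_area,
    polygon_centroid,
)

from conftest import circle_contour, circle_points, vertical_plane, zplane


def x_plane(x0: float) -> ImagePlane:
    """Vertical plane x = x0 (normal +x), transverse to z = const planes."""
    return ImagePlane((x0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))


def y_plane(y0: float) -> ImagePlane:
    """Vertical plane y = y0 (normal +y)."""
    return ImagePlane((0.0, y0, 0.0), (0.0, 0.0, 1.0), (1.0, 0.0, 0.0))


# -- areas and centroids ----------------------------------------------------


class TestPolygonArea:
    def test_unit_square(self, unit_square):
        assert polygon_area(unit_square) == pytest.approx(1.0, abs=1e-12)

    def test_regular_64gon_closed_form(self):
        # inscribed n-gon area is (n/2) r^2 sin(2 pi / n)
        c = circle_contour(0.0, 20.0, n=64)
        expected = 32.0 * 400.0 * np.sin(2.0 * np.pi / 64.0)
        assert polygon_area(c) == pytest.approx(expected, rel=1e-12)
        assert polygon_area(c) == pytest.approx(1254.6, abs=0.1)

    def test_orientation_independent(self):
        pts = np.array([[0, 0], [3, 1], [4, 4], [1, 5], [-1, 2]], dtype=float)
        a_fwd = polygon_area(PlanarContour(zplane(0.0), pts))
        a_rev = polygon_area(PlanarContour(zplane(0.0), pts[::-1]))
        assert a_fwd == pytest.approx(a_rev, rel=1e-14)

    @pytest.mark.parametrize("pts", [
        [[0, 0], [1, 0]],                      # two points
        [[0, 0], [1, 0], [2, 0]],              # collinear, zero area
        [[0, 0], [1, 0], [0, 0], [1, 0]],      # duplicates only
    ])
    def test_degenerate_rejected(self, pts):
        with pytest.raises(InvalidGeometryError):
            PlanarContour(zplane(0.0), np.array(pts, dtype=float))

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float)
        with pytest.raises(InvalidGeometryError):
            PlanarContour(zplane(0.0), bowtie)


class TestPolygonCentroid:
    def test_unit_square(self, unit_square):
        assert polygon_centroid(unit_square) == pytest.approx([0.5, 0.5, 0.0])

    def test_offcenter_circle(self):
        c = circle_contour(0.0, 7.0, n=128, center=(10.0, -5.0))
        assert polygon_centroid(c) == pytest.approx([10.0, -5.0, 0.0], abs=1e-6)

    def test_l_shaped_hexagon(self):
        # two-rectangle decomposition: centroid (5/6, 5/6)
        pts = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], dtype=float)
        c = PlanarContour(zplane(0.0), pts)
        assert polygon_centroid(c) == pytest.approx([5.0 / 6.0, 5.0 / 6.0, 0.0])

    def test_maps_to_patient_coordinates(self, unit_square):
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        t = np.array([5.0, -2.0, 7.0])
        moved = unit_square.transformed(R, t)
        assert polygon_centroid(moved) == pytest.approx(R @ [0.5, 0.5, 0.0] + t)


# -- plane/contour intersection and chords ---------------------------------


class TestPlaneContourIntersection:
    def test_circle_cut_through_center(self):
        c = circle_contour(0.0, 20.0, n=4096)
        pts = plane_contour_intersection(c, x_plane(0.0))
        assert pts.shape == (2, 3)
        assert pts[:, 1] == pytest.approx([-20.0, 20.0], abs=1e-4)
        assert pts[:, 0] == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_disjoint_cut_is_empty(self):
        c = circle_contour(0.0, 20.0)
        assert len(plane_contour_intersection(c, x_plane(25.0))) == 0

    def test_parallel_plane_raises(self):
        c = circle_contour(0.0, 20.0)
        with pytest.raises(NoIntersectionError):
            plane_contour_intersection(c, zplane(5.0))

    def test_vertex_on_plane_counts_once(self):
        square = PlanarContour(zplane(0.0),
                               np.array([[0, -1], [1, 0], [0, 1], [-1, 0]], float))
        pts = plane_contour_intersection(square, x_plane(0.0))
        assert pts.shape == (2, 3)

    @given(st.integers(0, 999))
    def test_matches_bruteforce_edge_oracle(self, idx):
        """Random star polygons: crossings equal per-edge 3-D segment/plane cuts."""
        rng = np.random.default_rng(idx)
        n = int(rng.integers(5, 40))
        phi = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
        if np.min(np.diff(phi)) < 1e-3:
            return
        r = rng.uniform(5.0, 30.0, n)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        try:
            contour = PlanarContour(zplane(0.0), pts)
        except InvalidGeometryError:
            return
        x0 = rng.uniform(-15.0, 15.0)
        cut = x_plane(x0)
        got = plane_contour_intersection(contour, cut, tol=1e-9)

        # oracle: intersect each closed 3-D edge with the plane x = x0
        p3 = contour.points3d
        expected = []
        for i in range(len(p3)):
            a, b = p3[i], p3[(i + 1) % len(p3)]
            da, db = a[0] - x0, b[0] - x0
            if da == 0.0:
                expected.append(a)
            if da * db < 0.0:
                expected.append(a + da / (da - db) * (b - a))
        expected = np.array(expected)
        assert len(got) == len(expected)
        if len(expected):
            order = np.argsort(expected[:, 1], kind="stable")
            assert got[:, 1] == pytest.approx(expected[order][:, 1], abs=1e-7)


class TestChordThrough:
    def test_diameter(self):
        c = circle_contour(0.0, 20.0, n=4096)
        assert chord_through(c, x_plane(0.0)).length == pytest.approx(40.0, abs=1e-3)

    def test_offcenter_chord_formula(self):
        c = circle_contour(0.0, 20.0, n=4096)
        expected = 2.0 * np.sqrt(400.0 - 144.0)
        assert chord_through(c, x_plane(12.0)).length == pytest.approx(expected, abs=1e-2)

    def test_outermost_pair_with_indentation(self):
        # C-shaped contour: a papillary-like notch makes x = 0 cross 4 times
        pts2d = np.array([[-20, -20], [20, -20], [20, -5], [-5, -5],
                          [-5, 5], [20, 5], [20, 20], [-20, 20]], dtype=float)
        c = PlanarContour(zplane(0.0), pts2d)
        pts = plane_contour_intersection(c, x_plane(0.0))
        assert len(pts) == 4
        assert pts[:, 1] == pytest.approx([-20.0, -5.0, 5.0, 20.0])
        chord = chord_through(c, x_plane(0.0))
        seps = [np.linalg.norm(p - q) for p in pts for q in pts]
        assert chord.length == pytest.approx(40.0, rel=1e-12)
        assert chord.length == pytest.approx(max(seps), rel=1e-12)

    def test_missing_chord_raises(self):
        c = circle_contour(0.0, 20.0)
        with pytest.raises(MissingChordError):
            chord_through(c, x_plane(25.0))


# -- slab clipping ----------------------------------------------------------


class TestClipBetweenPlanes:
    def test_rectangle_slab(self):
        rect = PlanarContour(zplane(0.0),
                             np.array([[-20, -30], [20, -30], [20, 30], [-20, 30]], float))
        clipped = clip_contour_between_planes(rect, y_plane(0.0), y_plane(10.0))
        assert polygon_area(clipped) == pytest.approx(400.0, rel=1e-12)

    def test_ellipse_zone_matches_quadrature(self):
        a, b = 20.0, 30.0  # 40 mm wide, 60 mm tall
        phi = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
        ell = PlanarContour(zplane(0.0),
                            np.column_stack([a * np.cos(phi), b * np.sin(phi)]))
        clipped = clip_contour_between_planes(ell, y_plane(0.0), y_plane(10.0))
        ys = np.linspace(0.0, 10.0, 20001)
        expected = np.trapezoid(2.0 * a * np.sqrt(1.0 - (ys / b) ** 2), ys)
        assert polygon_area(clipped) == pytest.approx(expected, rel=1e-4)

    def test_disjoint_slab_raises(self):
        c = circle_contour(0.0, 20.0)
        with pytest.raises(EmptyRegionError):
            clip_contour_between_planes(c, y_plane(30.0), y_plane(40.0))

    def test_slab_partition_reconstructs_area(self):
        c = circle_contour(0.0, 20.0, n=512)
        cuts = [-20.0, -7.0, 0.0, 5.0, 20.0]
        total = sum(
            polygon_area(clip_contour_between_planes(c, y_plane(lo), y_plane(hi)))
            for lo, hi in zip(cuts, cuts[1:])
        )
        assert total == pytest.approx(polygon_area(c), rel=1e-6)


# -- angles -----------------------------------------------------------------


class TestAnglePlaneToLine:
    @pytest.mark.parametrize("direction,expected", [
        ((0.0, 0.0, 1.0), np.pi / 2),   # along the normal
        ((1.0, 1.0, 0.0), 0.0),         # in the plane
        ((1.0, 0.0, 1.0), np.pi / 4),   # 45 degrees
    ])
    def test_reference_angles(self, direction, expected):
        line = LineSegment3((0.0, 0.0, 0.0), direction)
        assert angle_plane_to_line(line, zplane(0.0)) == pytest.approx(expected, abs=1e-12)

    def test_zero_length_raises(self):
        with pytest.raises(InvalidGeometryError):
            angle_plane_to_line(LineSegment3((1, 2, 3), (1, 2, 3)), zplane(0.0))


# -- invariance properties --------------------------------------------------


@given(st.integers(0, 499), st.floats(0.2, 4.0))
def test_area_rigid_invariance_and_scaling(idx, s):
    """Area is rigid-motion invariant and scales as s^2 under uniform scaling."""
    rng = np.random.default_rng(idx)
    n = int(rng.integers(4, 24))
    phi = np.sort(rng.uniform(0.0, 2.0 * np.pi, n))
    if np.min(np.diff(phi)) < 1e-2:
        return
    r = rng.uniform(3.0, 25.0, n)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    c = PlanarContour(zplane(0.0), pts)
    # a rigid motion of the plane frame leaves in-plane geometry untouched
    from scipy.spatial.transform import Rotation
    R = Rotation.from_euler("xyz", rng.uniform(-180, 180, 3), degrees=True).as_matrix()
    moved = c.transformed(R, rng.uniform(-50, 50, 3))
    assert polygon_area(moved) == pytest.approx(polygon_area(c), rel=1e-12)
    scaled = PlanarContour(zplane(0.0), pts * s)
    assert polygon_area(scaled) == pytest.approx(s**2 * polygon_area(c), rel=1e-9)


def test_chord_endpoints_lie_on_both_planes():
    c = circle_contour(0.0, 20.0, n=512)
    cut = x_plane(5.0)
    chord = chord_through(c, cut)
    assert abs(cut.signed_distance(chord.a)[0]) < 1e-9
    assert abs(c.plane.signed_distance(chord.b)[0]) < 1e-9
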