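"""Tolerance-aware planar/3-D geometry kernel.

All coordinates are millimetres in a right-handed patient coordinate system.
An image plane is stored as an origin plus an orthonormal in-plane frame
(``axis_u``, ``axis_v``); its normal is ``u x v``.  Contours are closed simple
polygons given by ordered 2-D in-plane points; orientation is normalized
counter-clockwise on construction so that delineation tools may emit either
winding.  Non-simple polygons are rejected, not repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    EmptyRegionError,
    InvalidGeometryError,
    MissingChordError,
    NoIntersectionError,
)

#: orthonormality tolerance for plane frames
ORTHO_TOL = 1e-9
#: angular tolerance (radians) below which two planes count as parallel
PARALLEL_TOL = 1e-6
#: default merge/snapping tolerance for intersection points (mm)
MERGE_TOL = 1e-6


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise InvalidGeometryError("zero-length vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class ImagePlane:
    """Oriented plane in patient space carrying a 2-D in-plane frame.

    Parameters
    ----------
    origin : (3,) array
        A point on the plane (mm).
    axis_u, axis_v : (3,) arrays
        Orthonormal unit vectors spanning the plane.  The plane normal is
        ``cross(axis_u, axis_v)``.
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "axis_u", np.asarray(self.axis_u, dtype=float).reshape(3))
        object.__setattr__(self, "axis_v", np.asarray(self.axis_v, dtype=float).reshape(3))
        u, v = self.axis_u, self.axis_v
        if abs(np.linalg.norm(u) - 1.0) > 1e-7 or abs(np.linalg.norm(v) - 1.0) > 1e-7:
            raise InvalidGeometryError("plane axes must be unit vectors")
        if abs(float(u @ v)) > 1e-7:
            raise InvalidGeometryError("plane axes must be orthogonal")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.axis_u, self.axis_v)

    def to_3d(self, pts2d: np.ndarray) -> np.ndarray:
        """Map (n, 2) in-plane coordinates to (n, 3) patient coordinates."""
        pts2d = np.atleast_2d(np.asarray(pts2d, dtype=float))
        return self.origin + pts2d[:, :1] * self.axis_u + pts2d[:, 1:2] * self.axis_v

    def to_2d(self, pts3d: np.ndarray) -> np.ndarray:
        """Project (n, 3) patient coordinates into the in-plane frame."""
        pts3d = np.atleast_2d(np.asarray(pts3d, dtype=float))
        rel = pts3d - self.origin
        return np.column_stack([rel @ self.axis_u, rel @ self.axis_v])

    def signed_distance(self, pts3d: np.ndarray) -> np.ndarray:
        pts3d = np.atleast_2d(np.asarray(pts3d, dtype=float))
        return (pts3d - self.origin) @ self.normal

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ImagePlane":
        """Return the plane after the rigid motion ``x -> R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return ImagePlane(R @ self.origin + t, R @ self.axis_u, R @ self.axis_v)


def make_axis_aligned_plane(z: float) -> ImagePlane:
    """Convenience: plane z = const with frame (x-hat, y-hat)."""
    return ImagePlane(np.array([0.0, 0.0, z]), np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))


@dataclass(frozen=True)
class LineSegment3:
    """Line segment between two 3-D points (mm)."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float).reshape(3))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float).reshape(3))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.b - self.a))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.a + self.b)


def _shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class PlanarContour:
    """Closed simple polygon lying in one image plane.

    ``points`` are ordered 2-D in-plane coordinates (mm); closure is implicit
    (the first point is not repeated).  Orientation is normalized CCW in the
    (u, v) frame at construction.
    """

    plane: ImagePlane
    points: np.ndarray
    surface: str = "endocardium"
    phase: str = "ED"
    slice_index: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidGeometryError("contour points must be an (n, 2) array")
        # drop an explicitly repeated closing point
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(np.unique(np.round(pts, 9), axis=0)) < 3:
            raise InvalidGeometryError("degenerate polygon: fewer than 3 distinct points")
        area2 = _shoelace(pts)
        if abs(area2) < 1e-12:
            raise InvalidGeometryError("degenerate polygon: zero signed area")
        poly = _ShapelyPolygon(pts)
        if not poly.is_valid or not poly.is_simple:
            raise InvalidGeometryError("non-simple (self-intersecting) polygon rejected")
        if area2 < 0.0:  # normalize CCW
            pts = pts[::-1]
        self.points = pts

    @property
    def points3d(self) -> np.ndarray:
        return self.plane.to_3d(self.points)

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.points)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PlanarContour":
        """Rigidly move the contour (plane frame moves; in-plane points fixed)."""
        return replace(self, plane=self.plane.transformed(rotation, translation),
                       points=self.points.copy())


def polygon_area(contour: PlanarContour) -> float:
    """Absolute shoelace area (mm^2) of the contour in its in-plane frame."""
    return abs(_shoelace(contour.points))


def polygon_centroid(contour: PlanarContour) -> np.ndarray:
    """Area-weighted centroid mapped back to 3-D patient coordinates (mm)."""
    pts = contour.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    cx = float(np.sum((x + xn) * cross)) / (6.0 * area)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * area)
    return contour.plane.to_3d(np.array([[cx, cy]]))[0]


def _intersection_line_2d(contour_plane: ImagePlane, cutting: ImagePlane):
    """Express the line (cutting plane) ∩ (contour plane) in the contour's frame.

    Returns (a, b, e) with the line ``a*x + b*y = e`` where (a, b) is a unit
    2-D gradient, so that ``a*x + b*y - e`` is a signed in-plane distance (mm).
    """
    n = cutting.normal
    a = float(n @ contour_plane.axis_u)
    b = float(n @ contour_plane.axis_v)
    g = float(np.hypot(a, b))  # sin of the dihedral angle between the planes
    if g < PARALLEL_TOL:
        raise NoIntersectionError("cutting plane is parallel to the contour's plane")
    e = float(n @ (cutting.origin - contour_plane.origin)) / g
    return a / g, b / g, e


def plane_contour_intersection(
    contour: PlanarContour, cutting: ImagePlane, tol: float = MERGE_TOL
) -> np.ndarray:
    """Intersect the polygon boundary with a cutting plane.

    Returns an (k, 3) array of patient-space points sorted along the
    intersection line (possibly empty).  Points closer than ``tol`` (mm) are
    merged and a vertex lying exactly on the cutting plane counts once.
    """
    a, b, e = _intersection_line_2d(contour.plane, cutting)
    pts = contour.points
    s = pts @ np.array([a, b]) - e
    s = np.where(np.abs(s) < tol, 0.0, s)

    hits: list[np.ndarray] = []
    n = len(pts)
    for i in range(n):
        if s[i] == 0.0:
            hits.append(pts[i])
        j = (i + 1) % n
        if s[i] * s[j] < 0.0:
            t = s[i] / (s[i] - s[j])
            hits.append(pts[i] + t * (pts[j] - pts[i]))
    if not hits:
        return np.empty((0, 3))

    hits_arr = np.array(hits)
    tdir = np.array([-b, a])  # direction along the intersection line
    order = np.argsort(hits_arr @ tdir, kind="stable")
    hits_arr = hits_arr[order]
    # merge points closer than tol along the line
    keep = [0]
    for i in range(1, len(hits_arr)):
        if np.linalg.norm(hits_arr[i] - hits_arr[keep[-1]]) > tol:
            keep.append(i)
    return contour.plane.to_3d(hits_arr[keep])


def chord_through(contour: PlanarContour, cutting: ImagePlane, tol: float = MERGE_TOL) -> LineSegment3:
    """Segment joining the two outermost crossings of the contour with the plane.

    This is the ventricular "diameter" for that cut.  With more than two
    crossings (e.g. papillary indentations) the outermost pair is chosen.
    """
    pts = plane_contour_intersection(contour, cutting, tol=tol)
    if len(pts) < 2:
        raise MissingChordError(
            f"cut yields {len(pts)} intersection point(s); need at least 2"
        )
    return LineSegment3(pts[0], pts[-1])


def clip_contour_between_planes(
    contour: PlanarContour, upper: ImagePlane, lower: ImagePlane
) -> PlanarContour:
    """Sub-polygon of ``contour`` lying in the slab between two parallel planes.

    The result is closed by the chord segments on each cutting plane.  If the
    slab splits the polygon into several pieces the largest is returned.
    """
    a1, b1, e1 = _intersection_line_2d(contour.plane, upper)
    a2, b2, e2 = _intersection_line_2d(contour.plane, lower)
    g = np.array([a1, b1])
    # align the second gradient with the first (planes are parallel)
    if a1 * a2 + b1 * b2 < 0.0:
        e2 = -e2
    lo, hi = sorted((e1, e2))
    if hi - lo < MERGE_TOL:
        raise EmptyRegionError("cutting planes coincide; empty slab")

    pts = contour.points
    span = float(np.max(np.abs(pts))) + abs(lo) + abs(hi) + 10.0
    d = np.array([-b1, a1])
    strip = _ShapelyPolygon(
        [g * lo + d * span, g * hi + d * span, g * hi - d * span, g * lo - d * span]
    )
    inter = contour.shapely().intersection(strip)
    polys = []
    if inter.geom_type == "Polygon" and not inter.is_empty:
        polys = [inter]
    elif inter.geom_type in ("MultiPolygon", "GeometryCollection"):
        polys = [p for p in inter.geoms if p.geom_type == "Polygon" and p.area > MERGE_TOL]
    if not polys:
        raise EmptyRegionError("clip region lies entirely outside the contour")
    best = max(polys, key=lambda p: p.area)
    new_pts = np.asarray(best.exterior.coords)[:-1]
    return PlanarContour(
        plane=contour.plane,
        points=new_pts,
        surface=contour.surface,
        phase=contour.phase,
        slice_index=contour.slice_index,
    )


def clip_contour_halfplane(
    contour: PlanarContour, cutting: ImagePlane, keep_side: np.ndarray
) -> PlanarContour:
    """Clip ``contour`` to the side of ``cutting`` indicated by 3-D direction ``keep_side``.

    Implemented as a slab clip against a far virtual plane placed beyond the
    contour's extent on the kept side.
    """
    keep_side = _unit(np.asarray(keep_side, dtype=float))
    extent = float(np.max(np.linalg.norm(contour.points3d - cutting.origin, axis=1))) + 10.0
    far = ImagePlane(cutting.origin + keep_side * extent, cutting.axis_u, cutting.axis_v)
    return clip_contour_between_planes(contour, cutting, far)


def angle_plane_to_line(line: LineSegment3, plane: ImagePlane) -> float:
    """Acute angle (radians, in [0, pi/2]) between a line and a plane.

    Zero when the line lies in the plane; pi/2 along the plane normal.
    """
    d = line.b - line.a
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise InvalidGeometryError("zero-length line has no direction")
    sin_phi = abs(float(plane.normal @ d)) / norm
    return float(np.arcsin(np.clip(sin_phi, 0.0, 1.0)))
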