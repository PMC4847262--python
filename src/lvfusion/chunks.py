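"""SAX/LAX chunk decomposition.

A stack of N parallel short-axis (SAX) contours plus one long-axis (LAX)
contour divides the left ventricle into consecutive "chunks": one interior
chunk per adjacent SAX pair, one apical chunk below the most apical SAX plane
(the LAX cross-section there is triangle-like, closing at the apex), and
optionally one *virtual* basal chunk built from the LAX segments that extend
above the most basal SAX plane.  Each chunk carries the geometric quantities
the volume models consume: the SAX areas bounding it, the LAX cross-sectional
area clipped to the chunk's slab, the two LAX-derived diameters at the
bounding planes, and the obliquity angle between the chunk axis (the line
joining the SAX centroids) and the LAX image plane.

Diameters are taken from the LAX contour (not the SAX rings): long-axis
slices suffer less partial-volume blurring, particularly near the apex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DecompositionError,
    EmptyRegionError,
    InvalidGeometryError,
    InvalidObliquityError,
    MissingChordError,
)
from .geometry import (
    PARALLEL_TOL,
    ImagePlane,
    LineSegment3,
    PlanarContour,
    angle_plane_to_line,
    chord_through,
    clip_contour_between_planes,
    clip_contour_halfplane,
    polygon_area,
    polygon_centroid,
)

KIND_BASAL_VIRTUAL = "basal_virtual"
KIND_INTERIOR = "interior"
KIND_APICAL = "apical"


@dataclass
class ContourStack:
    """One SAX contour stack plus one LAX contour (same surface and phase).

    ``sax`` is ordered base -> apex.  ``slice_thickness`` (t) and
    ``inter_slice_gap`` (l) are the acquisition extents in mm; per-slice
    extents can also be derived from the plane positions.
    """

    sax: list[PlanarContour]
    lax: PlanarContour | None = None
    slice_thickness: float | None = None
    inter_slice_gap: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sax:
            raise InvalidGeometryError("stack needs at least one SAX contour")
        n0 = self.sax[0].plane.normal
        for c in self.sax[1:]:
            sin_ang = float(np.linalg.norm(np.cross(n0, c.plane.normal)))
            if sin_ang > PARALLEL_TOL:
                raise InvalidGeometryError("SAX planes are not mutually parallel")
        contours = list(self.sax) + ([self.lax] if self.lax is not None else [])
        surfaces = {c.surface for c in contours}
        phases = {c.phase for c in contours}
        if len(surfaces) > 1 or len(phases) > 1:
            raise InvalidGeometryError("all contours must share surface and phase")
        idx = [c.slice_index for c in self.sax]
        if all(i is not None for i in idx) and len(idx) > 1:
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise InvalidGeometryError("SAX slice_index must strictly increase base->apex")

    @property
    def n_sax(self) -> int:
        return len(self.sax)

    @property
    def axis(self) -> np.ndarray:
        """Unit vector along the stack normal pointing base -> apex."""
        n = self.sax[0].plane.normal
        if len(self.sax) > 1:
            d = float((self.sax[-1].plane.origin - self.sax[0].plane.origin) @ n)
            if d < 0:
                n = -n
        return n / np.linalg.norm(n)

    @property
    def positions(self) -> np.ndarray:
        """Plane positions (mm) along the base->apex axis, increasing apexward."""
        ax = self.axis
        return np.array([float(c.plane.origin @ ax) for c in self.sax])

    def surface_label(self) -> str:
        return self.sax[0].surface

    def phase_label(self) -> str:
        return self.sax[0].phase


@dataclass
class ChunkGeometry:
    """Geometric summary of one inter-slice LV chunk.

    Index 0 is reserved for the basal virtual chunk, interior chunks run
    1..N-1 and the apical chunk is index N.  For the apical chunk the lower
    diameter and area are zero by definition; for the basal virtual chunk the
    upper fields mirror the lower ones.
    """

    index: int
    kind: str
    upper_area: float
    lower_area: float
    lax_area: float
    d_upper: float
    d_lower: float
    obliquity: float
    upper_contour: PlanarContour | None = field(default=None, repr=False)
    lower_contour: PlanarContour | None = field(default=None, repr=False)
    lax_plane: ImagePlane | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.upper_area, self.lower_area, self.lax_area) < 0:
            raise InvalidGeometryError("chunk areas must be non-negative")
        if min(self.d_upper, self.d_lower) < 0:
            raise InvalidGeometryError("chunk diameters must be non-negative")


def correct_lax_area(chunk: ChunkGeometry) -> ChunkGeometry:
    """Compensate an oblique LAX plane: scale the LAX area by cos(obliquity).

    An oblique long-axis plane (one that does not contain the chunk axis)
    cuts the chunk in a larger apparent area; multiplying by the cosine of
    the obliquity angle restores the axis-aligned cross-section.
    """
    if chunk.obliquity >= np.pi / 2:
        raise InvalidObliquityError("obliquity must be < pi/2")
    return replace(chunk, lax_area=chunk.lax_area * float(np.cos(chunk.obliquity)))


def _sax_chords(stack: ContourStack) -> list[LineSegment3]:
    chords = []
    for c in stack.sax:
        try:
            chords.append(chord_through(stack.lax, c.plane))
        except MissingChordError as exc:
            raise DecompositionError(
                f"LAX contour has no chord at SAX slice {c.slice_index}: {exc}"
            ) from exc
    return chords


def build_chunks(stack: ContourStack, include_basal_virtual: bool = False) -> list[ChunkGeometry]:
    """Decompose a stack into ordered (base -> apex) chunk geometries.

    Requires >= 2 SAX contours and a LAX contour transverse to the SAX planes
    that crosses every SAX plane of the stack.  The apical chunk is clipped
    from the LAX contour below the most apical SAX plane; if that clip is
    empty the chunk is omitted with a warning.  The basal virtual chunk (off
    by default) mirrors the basal slice's fields and uses the LAX segments
    above the most basal plane.
    """
    if stack.lax is None:
        raise DecompositionError("stack has no LAX contour")
    if stack.n_sax < 2:
        raise DecompositionError("need at least 2 SAX contours to form chunks")
    ang = angle_plane_to_line(
        LineSegment3(np.zeros(3), stack.axis), stack.lax.plane
    )
    # LAX plane must be transverse to SAX planes: the stack axis should lie
    # roughly within the LAX plane, never along its normal.
    if ang > np.pi / 2 - PARALLEL_TOL:
        raise DecompositionError("LAX plane is parallel to the SAX planes")

    areas = [polygon_area(c) for c in stack.sax]
    centroids = [polygon_centroid(c) for c in stack.sax]
    chords = _sax_chords(stack)
    ax = stack.axis
    n = stack.n_sax

    chunks: list[ChunkGeometry] = []

    if include_basal_virtual:
        try:
            basal_clip = clip_contour_halfplane(stack.lax, stack.sax[0].plane, -ax)
            axis_line = LineSegment3(centroids[0] - 10.0 * ax, centroids[0] + 10.0 * ax)
            if n >= 2:
                axis_line = LineSegment3(centroids[0], centroids[1])
            chunks.append(
                ChunkGeometry(
                    index=0,
                    kind=KIND_BASAL_VIRTUAL,
                    upper_area=areas[0],
                    lower_area=areas[0],
                    lax_area=polygon_area(basal_clip),
                    d_upper=chords[0].length,
                    d_lower=chords[0].length,
                    obliquity=angle_plane_to_line(axis_line, stack.lax.plane),
                    upper_contour=stack.sax[0],
                    lower_contour=stack.sax[0],
                    lax_plane=stack.lax.plane,
                )
            )
        except EmptyRegionError:
            warnings.warn("LAX contour does not extend above the most basal SAX plane; "
                          "basal virtual chunk omitted", RuntimeWarning, stacklevel=2)

    for i in range(1, n):
        upper_c, lower_c = stack.sax[i - 1], stack.sax[i]
        try:
            clip = clip_contour_between_planes(stack.lax, upper_c.plane, lower_c.plane)
        except EmptyRegionError as exc:
            raise DecompositionError(
                f"empty LAX clip between SAX slices {upper_c.slice_index} and "
                f"{lower_c.slice_index}"
            ) from exc
        chunks.append(
            ChunkGeometry(
                index=i,
                kind=KIND_INTERIOR,
                upper_area=areas[i - 1],
                lower_area=areas[i],
                lax_area=polygon_area(clip),
                d_upper=chords[i - 1].length,
                d_lower=chords[i].length,
                obliquity=angle_plane_to_line(
                    LineSegment3(centroids[i - 1], centroids[i]), stack.lax.plane
                ),
                upper_contour=upper_c,
                lower_contour=lower_c,
                lax_plane=stack.lax.plane,
            )
        )

    # apical chunk: LAX region below the most apical SAX plane, closing at
    # the apex taken from the LAX contour itself.
    try:
        apical_clip = clip_contour_halfplane(stack.lax, stack.sax[-1].plane, ax)
        lax_pts = stack.lax.points3d
        apex_pt = lax_pts[np.argmax(lax_pts @ ax)]
        chunks.append(
            ChunkGeometry(
                index=n,
                kind=KIND_APICAL,
                upper_area=areas[-1],
                lower_area=0.0,
                lax_area=polygon_area(apical_clip),
                d_upper=chords[-1].length,
                d_lower=0.0,
                obliquity=angle_plane_to_line(
                    LineSegment3(centroids[-1], apex_pt), stack.lax.plane
                ),
                upper_contour=stack.sax[-1],
                lower_contour=None,
                lax_plane=stack.lax.plane,
            )
        )
    except (EmptyRegionError, InvalidGeometryError):
        warnings.warn("LAX contour does not extend below the most apical SAX plane; "
                      "apical chunk omitted", RuntimeWarning, stacklevel=2)

    return chunks


def select_slice_subset(stack: ContourStack, n: int) -> ContourStack:
    """Retain ``n`` SAX slices covering the base-apex distance most uniformly.

    The most basal and most apical slices are always kept; the remaining
    n - 2 are the slices nearest the ideal uniform positions between them
    (ties resolved toward the base).  Spacing metadata is recomputed from the
    retained plane positions.
    """
    N = stack.n_sax
    if n > N or n < 2:
        raise DecompositionError(f"cannot select {n} slices from a stack of {N}")
    if n == N:
        return stack
    pos = stack.positions
    targets = pos[0] + (pos[-1] - pos[0]) * np.arange(n) / (n - 1)
    chosen: list[int] = []
    for t in targets:
        order = np.argsort(np.abs(pos - t), kind="stable")  # stable => ties basal
        for idx in order:
            if idx not in chosen:
                chosen.append(int(idx))
                break
    chosen = sorted(chosen)
    new_sax = []
    for new_idx, old_idx in enumerate(chosen):
        new_sax.append(replace(stack.sax[old_idx], slice_index=new_idx,
                               points=stack.sax[old_idx].points.copy()))
    spacings = np.diff(pos[chosen])
    mean_sp = float(np.mean(spacings))
    t = stack.slice_thickness if stack.slice_thickness is not None else mean_sp
    return ContourStack(
        sax=new_sax,
        lax=stack.lax,
        slice_thickness=t,
        inter_slice_gap=mean_sp - t,
        metadata=dict(stack.metadata, retained_indices=chosen),
    )


def drop_sax_without_chord(stack: ContourStack) -> ContourStack:
    """Drop SAX slices whose plane does not cross the LAX contour.

    Analog of the analyst's slice-selection rule: only slices in which the LV
    is visible on both views enter the decomposition.  Raises if fewer than
    two slices remain.
    """
    if stack.lax is None:
        return stack
    kept = []
    for c in stack.sax:
        try:
            chord_through(stack.lax, c.plane)
            kept.append(c)
        except MissingChordError:
            warnings.warn(
                f"SAX slice {c.slice_index} has no LAX chord; dropped", RuntimeWarning,
                stacklevel=2,
            )
    if len(kept) < 2:
        raise DecompositionError("fewer than 2 SAX slices intersect the LAX contour")
    kept = [replace(c, slice_index=i, points=c.points.copy()) for i, c in enumerate(kept)]
    return ContourStack(kept, stack.lax, stack.slice_thickness,
                        stack.inter_slice_gap, dict(stack.metadata))


def register_lax_to_sax(stack: ContourStack) -> ContourStack:
    """Optional rigid pre-step: translate the LAX contour in-plane so its
    midline passes through the mean SAX centroid.

    The decomposition itself fails loudly on misregistration; this helper is
    for stacks known to be off by a breath-hold shift.
    """
    if stack.lax is None:
        return stack
    mean_centroid = np.mean([polygon_centroid(c) for c in stack.sax], axis=0)
    target_u = float((mean_centroid - stack.lax.plane.origin) @ stack.lax.plane.axis_u)
    mids = []
    for c in stack.sax:
        try:
            mid = chord_through(stack.lax, c.plane).midpoint
            mids.append(float((mid - stack.lax.plane.origin) @ stack.lax.plane.axis_u))
        except MissingChordError:
            continue
    current_u = float(np.mean(mids)) if mids else float(np.mean(stack.lax.points[:, 0]))
    shifted = replace(stack.lax, points=stack.lax.points + np.array([target_u - current_u, 0.0]))
    return ContourStack(stack.sax, shifted, stack.slice_thickness,
                        stack.inter_slice_gap, dict(stack.metadata))
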