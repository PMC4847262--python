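"""Left-ventricular volume estimators.

Four families are provided:

* ``msimp_volume`` — modified Simpson: the LV as a stack of discs, one per
  SAX slice, each with volume ``A_i * (t + l)``.
* ``trapezoidal_volume`` — the SAX+LAX fusion model: each inter-slice chunk's
  volume is ``A_LAX * (A_up + A_low) / (d_up + d_low)``, with the apical
  chunk specialized to ``A_LAX * A_up / (2 d_up)`` (triangle-closed at the
  apex); the oblique-LAX cosine correction is applied per chunk.
* ``trapezoidal_integral_volume`` — the same model in numeric-integral form,
  rotating the equivalent trapezoid around the chunk axis and integrating the
  wedge volumes; serves as the reference for the closed form's mean-area
  approximation.
* ``classical_volume`` — classical few-slice geometric models from the
  echocardiography literature (single-plane/biplane area-length, Teichholz,
  hemisphere-cylinder).

Internal arithmetic is mm^3; reported volumes are ml (divided by 1000 at the
reporting boundary only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chunks import (
    KIND_APICAL,
    KIND_BASAL_VIRTUAL,
    ChunkGeometry,
    ContourStack,
    build_chunks,
    correct_lax_area,
)
from .errors import ConfigurationError, DegenerateChunkError, InvalidGeometryError
from .geometry import PlanarContour, polygon_area, _intersection_line_2d

logger = logging.getLogger("lvfusion")

MM3_PER_ML = 1000.0


@dataclass(frozen=True)
class VolumeEstimate:
    """A volume (ml) with its method tag and per-chunk/per-slice breakdown."""

    total: float
    per_chunk: tuple[tuple[int, float], ...]
    method: str
    n_slices_used: int

    def __post_init__(self) -> None:
        s = sum(v for _, v in self.per_chunk)
        if abs(self.total - s) > 1e-9 * max(1.0, abs(self.total)):
            raise InvalidGeometryError("total volume must equal the sum of its parts")
        if any(v < 0 for _, v in self.per_chunk):
            raise InvalidGeometryError("per-chunk volumes must be non-negative")


def _assemble(parts: list[tuple[int, float]], method: str, n_slices: int) -> VolumeEstimate:
    per_chunk = tuple((i, v / MM3_PER_ML) for i, v in parts)
    return VolumeEstimate(
        total=sum(v for _, v in per_chunk),
        per_chunk=per_chunk,
        method=method,
        n_slices_used=n_slices,
    )


def slice_extents(stack: ContourStack) -> np.ndarray:
    """Per-slice disc extents (mm) for the modified Simpson method.

    For a full, uniformly spaced acquisition this is ``t + l`` for every
    slice.  For subset stacks each retained slice's disc extends to the next
    retained plane; the most apical slice uses the mean of the other
    spacings (the acquisition no longer defines its extent).
    """
    n = stack.n_sax
    if n == 1:
        if stack.slice_thickness is None:
            raise ConfigurationError("single-slice stack needs slice_thickness (+ gap)")
        return np.array([stack.slice_thickness + (stack.inter_slice_gap or 0.0)])
    spacings = np.diff(stack.positions)
    if np.any(spacings <= 0):
        raise ConfigurationError("SAX plane positions are not strictly ordered base->apex")
    return np.append(spacings, np.mean(spacings))


def msimp_volume(stack: ContourStack) -> VolumeEstimate:
    """Modified Simpson volume: one disc per SAX slice, ``v_i = A_i * (t + l)``."""
    extents = slice_extents(stack)
    parts = [
        (i, polygon_area(c) * float(extents[i]))
        for i, c in enumerate(stack.sax)
    ]
    logger.info("msimp: %d slices, extents %s mm", stack.n_sax, np.round(extents, 3))
    return _assemble(parts, "msimp", stack.n_sax)


def trapezoidal_chunk_volume(chunk: ChunkGeometry, oblique_correction: bool = True) -> float:
    """Closed-form chunk volume (mm^3).

    Interior/basal chunks: ``A_LAX * (A_up + A_low) / (d_up + d_low)``.
    Apical chunk (``d_low = A_low = 0``): ``A_LAX * A_up / (2 d_up)``.
    The oblique-corrected LAX area is used whenever the obliquity is nonzero.
    """
    c = correct_lax_area(chunk) if (oblique_correction and chunk.obliquity > 0) else chunk
    if c.kind == KIND_APICAL:
        if c.d_upper <= 0:
            raise DegenerateChunkError(f"apical chunk {c.index}: zero upper diameter")
        return c.lax_area * c.upper_area / (2.0 * c.d_upper)
    denom = c.d_upper + c.d_lower
    if denom <= 0:
        raise DegenerateChunkError(f"chunk {c.index}: zero diameter sum")
    return c.lax_area * (c.upper_area + c.lower_area) / denom


def trapezoidal_volume(
    stack: ContourStack,
    include_basal_virtual: bool = False,
    oblique_correction: bool = True,
) -> VolumeEstimate:
    """Total trapezoidal-fusion volume: sum of chunk volumes base -> apex.

    The basal virtual chunk (mirrored fields above the most basal plane) is
    added only when ``include_basal_virtual`` is set; by default that volume
    is excluded, matching clinical practice where no reference standard
    exists for it.
    """
    chunks = build_chunks(stack, include_basal_virtual=include_basal_virtual)
    parts = [(c.index, trapezoidal_chunk_volume(c, oblique_correction)) for c in chunks]
    logger.info(
        "trapezoidal: %d SAX + 1 LAX, basal_virtual=%s, oblique_correction=%s, "
        "obliquities(deg)=%s",
        stack.n_sax, include_basal_virtual, oblique_correction,
        [round(np.degrees(c.obliquity), 2) for c in chunks],
    )
    return _assemble(parts, "trapezoidal", stack.n_sax + 1)


def _star_chord_length(points: np.ndarray, center: np.ndarray, direction: np.ndarray) -> float:
    """Full chord length of a closed polygon along a line through ``center``.

    The chord spans the outermost pair of boundary crossings.
    """
    d = direction / np.linalg.norm(direction)
    normal = np.array([-d[1], d[0]])
    s = (points - center) @ normal
    n = len(points)
    ts = []
    for i in range(n):
        j = (i + 1) % n
        si, sj = s[i], s[j]
        if si == 0.0:
            ts.append(float((points[i] - center) @ d))
        if si * sj < 0.0:
            t = si / (si - sj)
            p = points[i] + t * (points[j] - points[i])
            ts.append(float((p - center) @ d))
    if len(ts) < 2:
        return 0.0
    return max(ts) - min(ts)


def _chords_at_angles(contour: PlanarContour, theta0: float, thetas: np.ndarray) -> np.ndarray:
    """Chord lengths of a SAX contour through its centroid at angles theta0+thetas."""
    pts = contour.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    center = np.array(
        [float(np.sum((x + xn) * cross)), float(np.sum((y + yn) * cross))]
    ) / (6.0 * area)
    out = np.empty(len(thetas))
    for k, th in enumerate(thetas):
        ang = theta0 + th
        out[k] = _star_chord_length(pts, center, np.array([np.cos(ang), np.sin(ang)]))
    return out


def _lax_direction_in_sax_frame(chunk: ChunkGeometry, contour: PlanarContour) -> float:
    """Angle (in the SAX in-plane frame) of the LAX/SAX intersection line."""
    a, b, _ = _intersection_line_2d(contour.plane, chunk.lax_plane)
    # (a, b) is the in-plane gradient; the line direction is its perpendicular
    return float(np.arctan2(a, -b))


def trapezoidal_integral_volume(
    stack: ContourStack,
    n_theta: int = 360,
    include_basal_virtual: bool = False,
    oblique_correction: bool = True,
) -> VolumeEstimate:
    """Numeric-integral form of the trapezoidal fusion model.

    Per chunk, the equivalent trapezoid is rotated about the chunk axis and
    the wedge volumes are integrated over theta in [0, pi] by the trapezoid
    rule::

        V = 0.5 * A_LAX(0) / (d_up(0) + d_low(0))
            * \\int_0^pi ((d_up(theta) + d_low(theta)) / 2)^2  dtheta

    where d(theta) are full chords of the SAX polygons through the per-chunk
    axis (their centroids), measured from the LAX plane's direction.
    """
    if n_theta < 8:
        raise ConfigurationError("n_theta must be >= 8 for a usable quadrature")
    chunks = build_chunks(stack, include_basal_virtual=include_basal_virtual)
    thetas = np.linspace(0.0, np.pi, n_theta)
    parts: list[tuple[int, float]] = []
    for ch in chunks:
        c = correct_lax_area(ch) if (oblique_correction and ch.obliquity > 0) else ch
        theta0_up = _lax_direction_in_sax_frame(c, c.upper_contour)
        d_up = _chords_at_angles(c.upper_contour, theta0_up, thetas)
        if c.kind == KIND_APICAL:
            d_low = np.zeros_like(d_up)
            denom = c.d_upper
        elif c.kind == KIND_BASAL_VIRTUAL:
            d_low = d_up
            denom = c.d_upper + c.d_lower
        else:
            theta0_low = _lax_direction_in_sax_frame(c, c.lower_contour)
            d_low = _chords_at_angles(c.lower_contour, theta0_low, thetas)
            denom = c.d_upper + c.d_lower
        if denom <= 0:
            raise DegenerateChunkError(f"chunk {c.index}: zero diameter sum")
        integrand = ((d_up + d_low) / 2.0) ** 2
        integral = float(np.trapezoid(integrand, thetas))
        parts.append((c.index, 0.5 * c.lax_area / denom * integral))
    return _assemble(parts, "trapezoidal_integral", stack.n_sax + 1)


#: classical model labels -> required measurement names
CLASSICAL_MODELS = {
    "single-plane-ellipsoid": ("lax_area_mm2", "length_mm"),
    "biplane-ellipsoid": ("lax_area1_mm2", "lax_area2_mm2", "length_mm"),
    "teichholz": ("diameter_mm",),
    "hemisphere-cylinder": ("sax_area_mm2", "length_mm"),
}


def classical_volume(model: str, **measurements: float) -> float:
    """Classical few-slice LV volume (ml) from model-specific measurements.

    Formulas (echocardiography literature):

    * single-plane ellipsoid (area-length): ``V = 8 A^2 / (3 pi L)``
    * biplane ellipsoid: ``V = (8 / (3 pi)) A1 A2 / L``
    * Teichholz: ``V = 7.0 D^3 / (2.4 + D)`` with D in cm, V in ml
    * hemisphere-cylinder ("bullet"): ``V = (5/6) A L``
    """
    if model not in CLASSICAL_MODELS:
        raise ConfigurationError(
            f"unknown classical model {model!r}; choose from {sorted(CLASSICAL_MODELS)}"
        )
    required = CLASSICAL_MODELS[model]
    missing = [k for k in required if k not in measurements]
    if missing:
        raise ConfigurationError(f"{model} needs measurements {missing}")
    vals = {k: float(measurements[k]) for k in required}
    if any(v <= 0 for v in vals.values()):
        raise ConfigurationError(f"{model} measurements must be positive: {vals}")

    if model == "single-plane-ellipsoid":
        A, L = vals["lax_area_mm2"], vals["length_mm"]
        return 8.0 * A**2 / (3.0 * np.pi * L) / MM3_PER_ML
    if model == "biplane-ellipsoid":
        A1, A2, L = vals["lax_area1_mm2"], vals["lax_area2_mm2"], vals["length_mm"]
        return 8.0 / (3.0 * np.pi) * A1 * A2 / L / MM3_PER_ML
    if model == "teichholz":
        D = vals["diameter_mm"] / 10.0  # cm
        return 7.0 * D**3 / (2.4 + D)
    # hemisphere-cylinder
    A, L = vals["sax_area_mm2"], vals["length_mm"]
    return 5.0 / 6.0 * A * L / MM3_PER_ML
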