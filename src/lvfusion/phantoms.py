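"""Synthetic LV phantom laboratory.

Phantoms are star-shaped parametric surfaces about their long axis (z in the
local frame): every axial ray hits the surface exactly once, so any reslicing
yields simple closed contours and the enclosed volume has an exact or
oracle-computable value.  Four families are supported:

* ``ellipsoid`` — semi-axes (a, b, c); analytic volume 4/3 pi a b c.
* ``cylinder`` — elliptical cylinder of half-height c; analytic 2 pi a b c.
* ``superellipsoid`` — axial profile ``(1 - |z/c|^p)^(1/p)``; bullet-like for
  p > 2, a more LV-like shape than the pure ellipsoid.
* ``perturbed_ellipsoid`` — ellipsoid modulated by low-order radial harmonics
  ``1 + sum_k eps_k cos(k phi + psi_k)``; emulates the non-elliptical
  cross-sections of real hearts.

The module reslices phantoms into SAX stacks and LAX planes at arbitrary
orientations, simulates per-slice breath-hold misregistration, and runs the
slice-count ablation experiment (percent error of each estimator versus the
phantom ground truth at n = 4, 6, 8, 10, 12 slices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .chunks import ContourStack, drop_sax_without_chord, select_slice_subset
from .errors import ConfigurationError, DecompositionError, InvalidPhantomError
from .geometry import ImagePlane, PlanarContour
from .volumes import MM3_PER_ML, msimp_volume, trapezoidal_volume

FAMILIES = ("ellipsoid", "cylinder", "superellipsoid", "perturbed_ellipsoid")

#: base->apex coverage margin (fraction of the 2c extent trimmed per side);
#: ellipsoid-like shapes degenerate at the poles so the most basal/apical
#: "complete ring" planes sit slightly inside, the cylinder has full rings
#: at its exact ends.
DEFAULT_MARGIN_FRAC = {"cylinder": 0.0}
DEFAULT_MARGIN_FRAC_OTHER = 0.025

LAX_LABELS = {"4CH": 0.0, "2CH": 90.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric LV-like surface with computable ground-truth volume.

    ``harmonics`` is a tuple of (k, eps, psi) radial harmonic terms; each
    amplitude must be <= 0.15 and their sum < 1 so the surface stays
    star-shaped.  ``rotation_deg``/``translation`` give the rigid pose of the
    phantom in patient space (the local long axis is z).
    """

    family: str = "ellipsoid"
    a: float = 25.0
    b: float = 25.0
    c: float = 45.0
    z_exponent: float = 2.5
    harmonics: tuple[tuple[int, float, float], ...] = ()
    wall_thickness: float = 8.0
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidPhantomError(f"unknown phantom family {self.family!r}")
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidPhantomError("semi-axes must be positive")
        amps = [abs(e) for _, e, _ in self.harmonics]
        if any(e > 0.15 for e in amps):
            raise InvalidPhantomError("harmonic amplitudes must be <= 0.15")
        if sum(amps) >= 1.0:
            raise InvalidPhantomError("harmonic amplitudes sum must be < 1 (star-shape)")
        if self.family != "perturbed_ellipsoid" and self.harmonics:
            raise InvalidPhantomError("harmonics only apply to perturbed_ellipsoid")
        if self.z_exponent <= 0:
            raise InvalidPhantomError("z exponent must be positive")

    # -- local-frame surface -------------------------------------------------

    def profile(self, z: np.ndarray) -> np.ndarray:
        """Axial scaling f(z) of the cross-section, zero outside the body."""
        z = np.asarray(z, dtype=float)
        t = np.clip(np.abs(z) / self.c, 0.0, None)
        if self.family == "cylinder":
            return np.where(t <= 1.0, 1.0, 0.0)
        if self.family == "superellipsoid":
            p = self.z_exponent
        else:
            p = 2.0
        inside = np.clip(1.0 - t**p, 0.0, None)
        return inside ** (1.0 / p)

    def cross_base(self, phi: np.ndarray) -> np.ndarray:
        """Cross-section radius at f(z) = 1: elliptical radius x harmonics."""
        phi = np.asarray(phi, dtype=float)
        r = self.a * self.b / np.hypot(self.b * np.cos(phi), self.a * np.sin(phi))
        m = np.ones_like(r)
        for k, eps, psi in self.harmonics:
            m = m + eps * np.cos(k * phi + psi)
        return r * m

    def radius(self, z: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Star-shaped radius rho(z, phi) about the local long axis (mm)."""
        return self.profile(z) * self.cross_base(phi)

    @property
    def pose(self) -> tuple[np.ndarray, np.ndarray]:
        R = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()
        t = np.asarray(self.translation, dtype=float)
        return R, t

    def epicardial(self) -> "PhantomSpec":
        """Companion epicardial shell: all semi-axes grown by the wall thickness."""
        w = self.wall_thickness
        return replace(self, a=self.a + w, b=self.b + w, c=self.c + w)


def make_perturbed_ellipsoid(
    a: float, b: float, c: float, amplitude: float = 0.08, seed: int = 0, **kwargs
) -> PhantomSpec:
    """Perturbed ellipsoid with seeded low-order (k = 2, 3) radial harmonics."""
    rng = np.random.default_rng(seed)
    harmonics = tuple(
        (k, amplitude * scale * rng.uniform(0.4, 1.0), rng.uniform(0.0, 2.0 * np.pi))
        for k, scale in ((2, 1.0), (3, 0.6))
    )
    return PhantomSpec(family="perturbed_ellipsoid", a=a, b=b, c=c,
                       harmonics=harmonics, seed=seed, **kwargs)


def default_phantom_cohort(seed: int = 0, n: int = 5) -> list[PhantomSpec]:
    """A cohort of LV-like perturbed ellipsoids with realistic dimensions.

    Endocardial semi-axes are drawn around a ~110-150 ml end-diastolic
    cavity: a in 22-28 mm, b = a * U(0.85, 1), c in 40-50 mm, harmonic
    amplitude budget 0.08.
    """
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n):
        child_seed = int(child.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(child_seed)
        a = rng.uniform(22.0, 28.0)
        b = a * rng.uniform(0.85, 1.0)
        c = rng.uniform(40.0, 50.0)
        out.append(make_perturbed_ellipsoid(a, b, c, amplitude=0.08, seed=child_seed))
    return out


# -- ground truth -----------------------------------------------------------


def phantom_true_volume(spec: PhantomSpec, resolution: float = 0.5) -> float:
    """Ground-truth enclosed volume (ml).

    Pure ellipsoids and cylinders are analytic; other shapes are voxelized at
    the requested resolution (voxel-center counting, accuracy O(resolution)).
    """
    if resolution > 1.0:
        raise ConfigurationError("voxel resolution must be <= 1 mm")
    if spec.family == "ellipsoid":
        return 4.0 / 3.0 * np.pi * spec.a * spec.b * spec.c / MM3_PER_ML
    if spec.family == "cylinder":
        return 2.0 * np.pi * spec.a * spec.b * spec.c / MM3_PER_ML
    if spec.family == "perturbed_ellipsoid" and not spec.harmonics:
        return 4.0 / 3.0 * np.pi * spec.a * spec.b * spec.c / MM3_PER_ML

    # voxelize: the harmonic multiplier is z-independent, so a voxel center at
    # cylindrical (r, phi, z) is interior iff r / cross_base(phi) <= f(z).
    rmax = float(np.max(spec.cross_base(np.linspace(0, 2 * np.pi, 720)))) + resolution
    xs = np.arange(-rmax + resolution / 2, rmax, resolution)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    q = (np.hypot(X, Y) / spec.cross_base(np.arctan2(Y, X))).ravel()
    q.sort()
    zs = np.arange(-spec.c + resolution / 2, spec.c, resolution)
    f = spec.profile(zs)
    counts = np.searchsorted(q, f, side="right")
    return float(np.sum(counts)) * resolution**3 / MM3_PER_ML


def quadrature_volume(spec: PhantomSpec, n_z: int = 4001, n_phi: int = 2048) -> float:
    """High-resolution quadrature volume (ml): V = ∫∫ rho^2 / 2 dphi dz.

    Independent cross-check for the voxelization oracle (the profile and the
    angular factor separate for these phantoms).
    """
    zs = np.linspace(-spec.c, spec.c, n_z)
    phis = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    axial = float(np.trapezoid(spec.profile(zs) ** 2, zs))
    angular = float(np.mean(spec.cross_base(phis) ** 2)) * 2.0 * np.pi
    return 0.5 * axial * angular / MM3_PER_ML


# -- reslicing --------------------------------------------------------------


@dataclass(frozen=True)
class MotionModel:
    """Per-slice breath-hold displacement model.

    Each slice acquisition sees the heart displaced by an independent uniform
    draw: superior-inferior (along the local long axis) within ±max_si and
    anterior-posterior (transverse, local x) within ±max_ap.  Defaults follow
    reported respiratory heart displacement bounds (18 mm SI, 2.5 mm AP).
    """

    max_si: float = 18.0
    max_ap: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_si < 0 or self.max_ap < 0:
            raise ConfigurationError("displacement bounds must be >= 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        si = rng.uniform(-self.max_si, self.max_si, size=n)
        ap = rng.uniform(-self.max_ap, self.max_ap, size=n)
        return np.column_stack([si, ap])


def _lax_plane(angle_deg: float, tilt_deg: float) -> ImagePlane:
    """LAX plane through the local origin: rotated ``angle_deg`` about the long
    axis (4CH = 0, 2CH = 90) and optionally tilted ``tilt_deg`` about its
    in-plane transverse axis (an oblique LAX that no longer contains the
    long axis)."""
    alpha = np.radians(angle_deg)
    u = np.array([np.cos(alpha), np.sin(alpha), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    if tilt_deg:
        rot = Rotation.from_rotvec(np.radians(tilt_deg) * u).as_matrix()
        v = rot @ v
    return ImagePlane(np.zeros(3), u, v)


def _level_roots(spec, plane, offset, z, n_scan=256):
    """phi-roots of plane ∩ (displaced phantom level curve at height z)."""
    dz = z - offset[2]
    if spec.profile(np.array([dz]))[0] <= 0.0:
        return []
    n = plane.normal
    d = float(n @ plane.origin)

    def f(phi):
        rho = float(spec.radius(np.array([dz]), np.array([phi]))[0])
        x = offset[0] + rho * np.cos(phi)
        y = offset[1] + rho * np.sin(phi)
        return n[0] * x + n[1] * y + n[2] * z - d

    phis = np.linspace(0.0, 2.0 * np.pi, n_scan, endpoint=False)
    rho_s = spec.radius(np.full(n_scan, dz), phis)
    vals = (n[0] * (offset[0] + rho_s * np.cos(phis))
            + n[1] * (offset[1] + rho_s * np.sin(phis)) + n[2] * z - d)
    roots = []
    for i in range(n_scan):
        j = (i + 1) % n_scan
        a, bv = vals[i], vals[j]
        if a == 0.0:
            roots.append(float(phis[i]))
        elif a * bv < 0.0:
            lo, hi = phis[i], phis[i] + (phis[1] - phis[0])
            roots.append(float(brentq(f, lo, hi, xtol=1e-12)))
    pts = []
    for phi in roots:
        rho = float(spec.radius(np.array([dz]), np.array([phi]))[0])
        pts.append(np.array([offset[0] + rho * np.cos(phi),
                             offset[1] + rho * np.sin(phi), z]))
    return pts


def plane_section(
    spec: PhantomSpec,
    plane: ImagePlane,
    body_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_levels: int = 48,
) -> np.ndarray:
    """Closed cross-section polygon of a (possibly displaced) phantom.

    Works for any plane that is roughly longitudinal (not parallel to the
    cross-sections): the section is assembled from the plane's crossings of
    the phantom's z-level curves, with bisection refinement at the levels
    where the plane becomes tangent, and ordered by angle about the section
    centroid.  Returns (n, 2) in-plane coordinates in the plane's frame.
    """
    offset = np.asarray(body_offset, dtype=float)
    ts = np.linspace(0.0, np.pi, n_levels)
    levels = offset[2] + spec.c * np.cos(ts)  # cos-spaced, poles included
    pts3 = []
    has_roots = []
    for z in levels:
        pts = _level_roots(spec, plane, offset, z)
        pts3.extend(pts)
        has_roots.append(bool(pts))

    # refine turnaround levels (plane tangent to the surface between a level
    # with crossings and an empty neighbour)
    for i in range(len(levels) - 1):
        if has_roots[i] != has_roots[i + 1]:
            z_in = levels[i] if has_roots[i] else levels[i + 1]
            z_out = levels[i + 1] if has_roots[i] else levels[i]
            for _ in range(24):
                mid = 0.5 * (z_in + z_out)
                if _level_roots(spec, plane, offset, mid):
                    z_in = mid
                else:
                    z_out = mid
            pts3.extend(_level_roots(spec, plane, offset, z_in))

    # include a pole apex/base point when the surface closes there and the
    # plane passes through it (axis-containing LAX planes)
    if spec.profile(np.array([spec.c]))[0] == 0.0:
        for zp in (offset[2] + spec.c, offset[2] - spec.c):
            pole = np.array([offset[0], offset[1], zp])
            if abs(float(plane.normal @ (pole - plane.origin))) < 1e-9:
                pts3.append(pole)

    if len(pts3) < 3:
        raise DecompositionError("plane misses the phantom (no section)")
    pts2 = plane.to_2d(np.array(pts3))
    center = pts2.mean(axis=0)
    order = np.argsort(np.arctan2(pts2[:, 1] - center[1], pts2[:, 0] - center[0]),
                       kind="stable")
    pts2 = pts2[order]
    keep = [0]
    for i in range(1, len(pts2)):
        if np.linalg.norm(pts2[i] - pts2[keep[-1]]) > 1e-9:
            keep.append(i)
    if np.linalg.norm(pts2[keep[-1]] - pts2[keep[0]]) <= 1e-9:
        keep = keep[:-1]
    return pts2[keep]


def reslice(
    spec: PhantomSpec,
    sax_count: int,
    sax_spacing: float | None = None,
    lax_orientation: str | float = "4CH",
    *,
    lax_tilt_deg: float = 0.0,
    n_vertices: int = 96,
    margin_frac: float | None = None,
    z_base: float | None = None,
    z_apex: float | None = None,
    motion: MotionModel | None = None,
    motion_on_lax: bool = False,
    surface: str = "endocardium",
    phase: str = "ED",
) -> ContourStack:
    """Reslice a phantom into a SAX contour stack plus one LAX contour.

    SAX planes are perpendicular to the phantom's long axis and uniformly
    spaced base -> apex over [z_base, z_apex] (defaults: the long-axis extent
    minus a family-dependent complete-ring margin).  The LAX plane passes
    through (or, when tilted, near) the axis at the requested rotation:
    ``"4CH"`` = 0 deg, ``"2CH"`` = 90 deg, or any angle in degrees.  With a
    ``motion`` model each slice samples the phantom displaced by its own
    uniform breath-hold draw; slices whose plane then misses the phantom are
    omitted with a warning.

    By default the LAX acquisition is the spatial reference frame and is not
    displaced (``motion_on_lax=False``): contour sets are analysed after
    SAX/LAX registration, so only the residual per-slice scatter of the SAX
    stack — and the through-plane content change it causes — reaches the
    estimators.  Set ``motion_on_lax=True`` to also displace the LAX slice
    by its own draw (an unregistered acquisition).
    """
    if sax_count < 2:
        raise ConfigurationError("need at least 2 SAX planes")
    if margin_frac is None:
        margin_frac = DEFAULT_MARGIN_FRAC.get(spec.family, DEFAULT_MARGIN_FRAC_OTHER)
    trim = margin_frac * 2.0 * spec.c
    if z_base is None:
        z_base = spec.c - trim
    if z_apex is None:
        z_apex = -spec.c + trim
    if sax_spacing is None:
        sax_spacing = (z_base - z_apex) / (sax_count - 1)
    z_planes = z_base - sax_spacing * np.arange(sax_count)

    if isinstance(lax_orientation, str):
        try:
            lax_angle = LAX_LABELS[lax_orientation.upper()]
        except KeyError as exc:
            raise ConfigurationError(
                f"unknown LAX label {lax_orientation!r}; use 4CH/2CH or degrees"
            ) from exc
    else:
        lax_angle = float(lax_orientation)

    offsets_sax = np.zeros((sax_count, 2))
    offset_lax = np.zeros(2)
    if motion is not None:
        rng = np.random.default_rng(motion.seed)
        offsets_sax = motion.draw(rng, sax_count)
        if motion_on_lax:
            offset_lax = motion.draw(rng, 1)[0]

    phis = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    R, t = spec.pose
    sax_contours: list[PlanarContour] = []
    for i, z in enumerate(z_planes):
        d_si, d_ap = offsets_sax[i]
        z_eff = z - d_si
        if spec.profile(np.array([z_eff]))[0] <= 0.0:
            warnings.warn(f"SAX plane {i} misses the phantom; slice omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        rho = spec.radius(np.full(n_vertices, z_eff), phis)
        pts = np.column_stack([d_ap + rho * np.cos(phis), rho * np.sin(phis)])
        plane = ImagePlane(np.array([0.0, 0.0, z]),
                           np.array([1.0, 0.0, 0.0]),
                           np.array([0.0, 1.0, 0.0])).transformed(R, t)
        sax_contours.append(PlanarContour(plane, pts, surface=surface, phase=phase,
                                          slice_index=len(sax_contours)))
    if len(sax_contours) < 2:
        raise DecompositionError("fewer than 2 SAX planes intersect the phantom")

    lplane = _lax_plane(lax_angle, lax_tilt_deg)
    lax_pts = plane_section(
        spec, lplane,
        body_offset=(offset_lax[1], 0.0, offset_lax[0]),
        n_levels=max(32, n_vertices // 2),
    )
    lax = PlanarContour(lplane.transformed(R, t), lax_pts, surface=surface, phase=phase)

    meta = {
        "family": spec.family,
        "lax_angle_deg": lax_angle,
        "lax_tilt_deg": lax_tilt_deg,
        "z_base": float(z_base),
        "z_apex": float(z_apex),
    }
    if motion is not None:
        meta["motion_offsets_sax"] = offsets_sax.tolist()
        meta["motion_offsets_lax"] = offset_lax.tolist()
    return ContourStack(sax_contours, lax, slice_thickness=float(sax_spacing),
                        inter_slice_gap=0.0, metadata=meta)


def apply_breathhold_misregistration(stack: ContourStack, motion: MotionModel) -> ContourStack:
    """Rigidly translate each slice's contours by an independent motion draw.

    Contour shapes are preserved: each SAX slice moves along the long axis
    (superior-inferior draw) and transversely in-plane (anterior-posterior
    draw); the LAX contour receives its own draw, applied in-plane.
    Reproducible from the motion seed; the drawn offsets are recorded in the
    returned stack's metadata.  For motion amplitudes comparable to the slice
    spacing the displaced planes may reorder, in which case downstream
    decomposition fails loudly; phantom experiments instead simulate motion
    at reslice time (the heart is displaced before each slice is cut).
    """
    rng = np.random.default_rng(motion.seed)
    offsets = motion.draw(rng, stack.n_sax)
    lax_offset = motion.draw(rng, 1)[0]
    ax = stack.axis
    new_sax = []
    for c, (d_si, d_ap) in zip(stack.sax, offsets):
        plane = ImagePlane(c.plane.origin + d_si * ax, c.plane.axis_u, c.plane.axis_v)
        new_sax.append(replace(c, plane=plane, points=c.points + np.array([d_ap, 0.0])))
    new_lax = stack.lax
    if new_lax is not None:
        d_si, d_ap = lax_offset
        u, v = new_lax.plane.axis_u, new_lax.plane.axis_v
        shift2 = np.array([float(ax @ u), float(ax @ v)]) * d_si + np.array([d_ap, 0.0])
        new_lax = replace(new_lax, points=new_lax.points + shift2,
                          plane=new_lax.plane)
    meta = dict(stack.metadata, motion_offsets_sax=offsets.tolist(),
                motion_offsets_lax=lax_offset.tolist())
    return ContourStack(new_sax, new_lax, stack.slice_thickness,
                        stack.inter_slice_gap, meta)


# -- ablation experiment ----------------------------------------------------


def run_slice_ablation(
    specs: list[PhantomSpec] | PhantomSpec,
    n_values: list[int],
    methods: tuple[str, ...] = ("trapezoidal", "msimp"),
    repetitions: int = 1,
    seed: int = 0,
    base_slices: int = 12,
    motion: MotionModel | None = None,
    lax_orientation: str | float = "4CH",
    n_vertices: int = 96,
    resolution: float = 0.5,
    count_lax_in_n: bool = True,
    include_basal_virtual: bool = False,
) -> pd.DataFrame:
    """Percent-error table of volume estimators versus phantom ground truth.

    For each phantom a dense ``base_slices`` stack (plus one LAX) is cut,
    then per slice budget ``n`` the estimators run on the uniformly covering
    subset.  With ``count_lax_in_n`` (default) the trapezoidal model uses
    n - 1 SAX slices plus the LAX slice while mSimp uses n SAX slices, so
    both consume the same number of acquisitions.  With a ``motion`` model
    each repetition re-slices with fresh per-slice breath-hold draws (seeded
    reproducibly from ``seed``).

    Returns a tidy DataFrame with one row per
    (phantom, repetition, method, n): estimate, truth, percent error.
    """
    if isinstance(specs, PhantomSpec):
        specs = [specs]
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(specs) * max(1, repetitions)))
    rows = []
    for p_idx, spec in enumerate(specs):
        truth = phantom_true_volume(spec, resolution=resolution)
        for rep in range(max(1, repetitions)):
            child_seed = int(next(children).generate_state(1)[0] % 2**31)
            rep_motion = None
            if motion is not None:
                rep_motion = MotionModel(motion.max_si, motion.max_ap, seed=child_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                stack = reslice(spec, base_slices, lax_orientation=lax_orientation,
                                n_vertices=n_vertices, motion=rep_motion)
            for n in n_values:
                for method in methods:
                    est = _estimate_for(stack, method, n, count_lax_in_n,
                                        include_basal_virtual)
                    rows.append({
                        "phantom": p_idx,
                        "rep": rep,
                        "method": method,
                        "n_slices": n,
                        "estimate_ml": est,
                        "truth_ml": truth,
                        "error_pct": 100.0 * (est - truth) / truth,
                    })
    return pd.DataFrame(rows)


def _estimate_for(stack: ContourStack, method: str, n: int,
                  count_lax_in_n: bool, include_basal_virtual: bool) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "msimp":
            sub = select_slice_subset(stack, min(n, stack.n_sax))
            return msimp_volume(sub).total
        if method == "trapezoidal":
            n_sax = (n - 1) if count_lax_in_n else n
            sub = select_slice_subset(stack, min(n_sax, stack.n_sax))
            sub = drop_sax_without_chord(sub)
            return trapezoidal_volume(
                sub, include_basal_virtual=include_basal_virtual).total
    raise ConfigurationError(f"unknown ablation method {method!r}")


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD (n-1 denominator) of percent error per (method, n)."""
    g = table.groupby(["method", "n_slices"])["error_pct"]
    out = g.agg(mean_error_pct="mean", sd_error_pct=lambda s: s.std(ddof=1),
                n_cases="count").reset_index()
    return out
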