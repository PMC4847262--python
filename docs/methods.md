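# Methods

## The estimation problem

Cardiac MR protocols measure left-ventricular (LV) volumes from a stack of
parallel short-axis (SAX) cine slices, delineated at end-diastole (ED) and
end-systole (ES).  With a full stack (9–12 slices) the modified Simpson
(mSimp) disc summation is accurate; when slices are lost to motion artifacts
or the protocol is shortened for patients who cannot sustain repeated
breath-holds, disc models degrade quickly because each disc must stand in
for a thick, tapering segment of the ventricle.

`lvfusion` implements a fusion estimator that adds the information in one
long-axis (LAX) slice.  The N SAX planes divide the LV into consecutive
*chunks*; within each chunk the LAX cross-section supplies the shape of the
ventricle between the SAX planes, which the disc model has to guess.

## Volume models

**Modified Simpson.**  Per slice, `v_i = A_i (t + l)` with `A_i` the contour
area, `t` the slice thickness, `l` the inter-slice gap.  For subset stacks
(non-uniform retained planes) each disc extends to the next retained plane
and the most apical disc uses the mean of the other spacings — the
acquisition no longer defines its extent, so a rule is needed; this one
reduces to `t + l` on uniform full stacks.

**Trapezoidal SAX+LAX fusion.**  For chunk *i* between two SAX planes, let
`A_LAX` be the LAX contour area clipped to the chunk's slab, `d_up`, `d_low`
the chords of the LAX contour on the two planes (the LV "diameters" — they
are read from the LAX contour because long-axis slices suffer less
partial-volume blurring, especially at the apex), and `A_up`, `A_low` the
SAX contour areas.  Modelling every axial cross-section of the chunk as a
trapezoid of equal area and rotating it about the chunk axis gives the
closed form

    V_i = A_LAX (A_up + A_low) / (d_up + d_low).

The most apical chunk closes at the apex taken from the LAX contour itself:
`d_low = A_low = 0` and the cross-section is a triangle, giving
`V_N = A_LAX A_up / (2 d_up)`.  A *virtual* chunk above the most basal plane
(mirrored fields) can be added with `include_basal_virtual=True`; it is off
by default because clinical references provide no ground truth for it.

**Wedge-integral reference form.**  Before the mean-area approximation the
model reads

    V_i = 0.5 A_LAX / (d_up(0) + d_low(0)) ∫₀^π ((d_up(θ) + d_low(θ))/2)² dθ,

with `d(θ)` full chords of the SAX polygons through their centroids,
measured from the LAX plane.  `trapezoidal_integral_volume` evaluates this
by the composite trapezoid rule (default 360 angular samples; results change
by < 1e-4 relative between 180 and 360 on smooth shapes).  The closed form
replaces the integral — the area of the mean-diameter contour — by the mean
of the two SAX areas; that is an AM-versus-QM substitution, exact for
untapered chunks and increasingly generous as `A_up/A_low` departs from 1.
At the full 12-slice acquisition the two forms agree within ~1% on convex
phantoms; at 6 slices the taper pushes the gap to ~4%, which is a property
of the model pair, not a numerical artifact.

**Oblique-LAX correction.**  When the LAX plane does not contain the chunk
axis (obliquity Φ = the angle between the line joining the two SAX centroids
and the LAX plane; for the apical chunk the lower point is the LAX apex),
the apparent LAX area is inflated and is corrected by `A'_LAX = A_LAX cos Φ`.
With a 20° oblique plane the corrected estimate recovers the axis-aligned
one within ~1% on smooth phantoms, versus ~6% uncorrected.

**Classical few-slice models** (single-plane ellipsoid `8A²/3πL`, biplane
ellipsoid `(8/3π) A₁A₂/L`, Teichholz `7.0 D³/(2.4 + D)` with D in cm,
hemisphere-cylinder `(5/6) A L`) are standard echocardiography formulas,
included for comparison at 1–3 slices.  They are external constants, not
derived here.

Internal arithmetic is mm/mm²/mm³; volumes are converted to ml only at the
reporting boundary.  All SDs use the n−1 denominator.  Myocardial mass uses
the ED epicardial-minus-endocardial volume and a density of 1.05 g/ml
(configurable); the ED-only convention is an assumption, stated here.

## Geometry kernel

Planes are origin + orthonormal (u, v) frames in a right-handed patient
coordinate system (DICOM-style, millimetres); contours are ordered 2-D
in-plane point lists, normalized counter-clockwise at construction so either
delineation winding is accepted.  Non-simple polygons are rejected, not
repaired — repair is segmentation-tool territory.  Plane/polygon crossings
snap within 1e-6 mm so a vertex on the cutting plane counts once; with more
than two crossings (papillary indentations) the chord takes the outermost
pair, the package's documented choice where segmentation noise makes the
count ambiguous.  Slab clipping is delegated to Shapely; if a slab splits a
non-convex contour the largest piece is kept.

## The phantom laboratory

Phantoms are star-shaped parametric surfaces about their long axis
`ρ(z, φ) = f(z) · r_ellipse(φ) · (1 + Σ ε_k cos(kφ + ψ_k))`:

* `ellipsoid` (`f = √(1−(z/c)²)`) and `cylinder` (`f = 1`) have analytic
  volumes (4/3 πabc and 2πabc) and serve as exactness oracles.
* `superellipsoid` (`f = (1−|z/c|^p)^{1/p}`, default p = 2.5) is bullet-like
  and closer to a real LV's flat-based shape.
* `perturbed_ellipsoid` adds seeded low-order harmonics (k = 2, 3, each
  amplitude ≤ 0.15, star-shape enforced) emulating non-elliptical
  cross-sections.

Ground truth is analytic where available, otherwise a voxelization oracle at
0.5 mm (voxel-center counting; cross-checked in the tests against an
independent separable quadrature of ∫∫ ρ²/2 dφ dz to ~0.3%).

Reslicing places SAX planes perpendicular to the long axis, uniformly from
base to apex.  Ellipsoid-like shapes degenerate at the poles, so their
coverage trims 2.5% of the long-axis extent per side — the analog of
selecting the most basal slice with a complete endocardial ring; cylinders
keep full rings at their exact ends and use no margin.  The excluded polar
caps bound the trapezoidal error floor at roughly −0.3% on a full ellipsoid.
The LAX plane passes through the axis at a requested rotation (4CH = 0°,
2CH = 90°, or arbitrary degrees) and may be tilted about its transverse
axis to create a genuinely oblique plane; oblique sections are computed by
root-finding the plane's crossings of the phantom's z-level curves with
bisection refinement at tangency.  Contours default to 96 vertices, chosen
so polygon discretization error (~0.07% in area) stays well below model
error.

**Breath-hold misregistration.**  Each slice acquisition sees the heart
displaced by an independent uniform draw — superior-inferior along the long
axis (≤ 18 mm) and anterior-posterior transversely (≤ 2.5 mm), the reported
bounds of respiratory heart motion; the distribution is uniform because no
more specific shape is established, and rotation is not simulated.  The
displacement is applied to the phantom *before* the slice is cut, so a SAX
slice contains the cross-section from the displaced position on its nominal
plane — through-plane content change, not just a shifted outline.  Slices
whose plane then misses the phantom are omitted, and SAX slices without a
LAX chord are dropped before decomposition (the analyst's slice-selection
rule).  The LAX acquisition serves as the spatial reference frame by
default: contour sets are analysed after SAX/LAX registration, so only
residual per-slice SAX scatter reaches the estimators.  Displacing the LAX
too (`motion_on_lax=True`) truncates the usable SAX–LAX overlap by ~9 mm on
average and dominates every other error source — that regime measures the
absence of registration, not the estimator.  A contour-level rigid
translation op is also provided for generic stacks; note that at the full
18 mm bound it can reorder planes spaced ~15 mm apart, upon which the
decomposition fails loudly by design.

**What the phantoms do not emulate:** papillary muscles and trabeculation,
partial-volume blur, delineation error, a true mitral-valve base, regional
wall-motion abnormalities.  Passing phantom tests therefore demonstrates the
geometric fidelity of the estimators, not their clinical accuracy on
pathological anatomy.

## The ablation experiment

`run_slice_ablation` cuts a dense 12-slice stack per phantom, then evaluates
each estimator at slice budgets n ∈ {4, 6, 8, 10, 12}, selecting subsets
that always retain the most basal and most apical slices and cover the
distance between them most uniformly (ties resolved toward the base).
Budgets follow the clinical comparison convention: at a budget of n slices,
mSimp uses n SAX while the trapezoidal model uses n−1 SAX plus the LAX.
On the default five-phantom cohort (seeded perturbed ellipsoids around a
110–150 ml cavity) the trapezoidal mean error is roughly −3% at n = 4
converging to a few tenths of a percent, and beats mSimp's magnitude at
n = 4 and 6 — the ordering the estimator exists to deliver.

A note on derived parameters: on self-similar ED/ES phantom pairs the
estimators' relative errors cancel exactly in the ejection fraction (both
are scale-equivariant), so phantom EF errors are ~0 by construction; SV and
mass errors equal the underlying volume errors.

## Numerical choices and degenerate inputs

* Plane-parallel tolerance 1e-6 rad; frame orthonormality 1e-9;
  intersection merge tolerance 1e-6 mm.
* Chunks with zero diameter sums, empty clips, or missing chords raise
  typed errors naming the slice; the apical/basal virtual chunks degrade to
  warnings and omission when the LAX simply does not extend there.
* Estimator totals are exactly the sum of their per-chunk parts; everything
  scales as s³ under uniform scaling to 1e-9 relative.
* All randomness (phantom cohorts, motion draws) flows from explicit seeds
  via `numpy` generators; repeated runs are bit-identical.

## Problem sizes

Validation experiments use 5 phantoms × 5 slice budgets, 10 motion
repetitions, 96-vertex contours, 360 angular quadrature samples and a
0.5 mm voxel oracle; the full suite and the acceptance script each complete
in seconds on one CPU.
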