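# Methods

`rtrecur` implements a semi-automated recurrence-pattern analysis for
radiotherapy: given a planning CT with its structure set and per-plan dose
grids, plus a follow-up CT on which a local recurrence has been delineated,
it quantifies the dose the recurrence region received from each plan and
where the recurrence lies relative to the high-dose (boost) volume. This
note documents the models, conventions, numerical choices and limitations.

## Coordinate and transform conventions

All geometry lives in DICOM patient coordinates (LPS, millimetres). Voxel
indices are 0-based, with the grid origin at the *center* of voxel
(0, 0, 0); this removes the half-voxel ambiguity that plagues corner-based
conventions. Arrays are stored slice-major (`array[k, j, i]`).

A rigid motion is reported as the nine-component vector
`(tx, ty, tz, rpx, rpy, rpz, rx, ry, rz)`: translation (mm), rotation point
(mm) and rotation angles. Angles are **degrees**, intrinsic Euler angles in
z–y–x order (`R = Rz·Ry·Rx`), applied about the rotation point:

    p' = R (p − rp) + rp + t

Degrees vs radians and the axis order are genuinely open choices; both are
fixed here and declared in the transform's plain-text serialization header,
so a serialized transform is interpretable without reading the code. In a
registration the transform maps points of the fixed (planning) frame into
the moving (follow-up) frame — the resampling convention used by ITK — so
structures delineated on the follow-up scan are carried into the planning
frame through the *inverse* transform.

## Rigid registration

Follow-up scans of abdominal patients are often acquired in oblique (RAO)
positioning, giving axial rotations of 20–60° relative to the planning scan
— far beyond the capture range of any local optimizer. Registration is
therefore two-staged:

1. **Pre-initialization** aligns intensity centroids (weights are voxel
   values above the volume minimum, so air contributes nothing) and, when
   the operator supplies the approximate acquisition rotation as a hint,
   applies that axial rotation about the moving volume's centroid. This
   step is deterministic and cheap.
2. **Mutual-information refinement**: Mattes mutual information (50
   histogram bins, 25% random sampling), a 3-level shrink/smooth pyramid,
   and a regular-step gradient-descent optimizer (initial step 2 mm,
   ≤200 iterations/level, parameter scales from physical shift), run
   through ITK. All settings are exposed in `RegistrationParams`.

The rotation point defaults to the image center; the pipeline moves it to
the PTV centroid when a PTV structure is available, since the clinical
registration is judged around the target and spinal cord. Structure-guided
registration is available as an optional metric mask (the union of chosen
structures dilated by 10 mm), default off — how exactly the original
clinical workflow constrained its registration is not specified anywhere,
so the least-assuming variant is the default.

Determinism: the metric's random sampling is seeded (a seed of 0 is shifted
internally, since the underlying library interprets 0 as "use the clock"),
and the registration runs single-threaded, so identical seeds give
bit-identical transform parameters. Divergence (the metric worsening
monotonically through an entire pyramid level) raises an error carrying the
best transform seen.

A manual override transform in the case configuration bypasses the
automatic registration entirely; this stands in for the interactive
revision step of a semi-automated workflow.

## Subvoxel voxelization

Structures are kept as closed planar polygons in physical millimetres until
the last moment and only voxelized on the analysis grid, after any
transforms. Each axial slice is rasterized with the even-odd rule on an
in-plane subgrid of factor 2^level; a voxel's occupancy is the fraction of
its subcells inside the polygon(s). Levels 0–3 (factors 1, 2, 4, 8) are
tried in order until the total volume changes by less than 0.5% (relative)
between consecutive levels; the achieved level is recorded. Supersampling
is in-plane only, matching the slice-wise nature of contour data — there is
no subslice information to recover in z.

Degenerate inputs are handled explicitly rather than rejected:
self-intersecting polygons are processed by the even-odd rule with a
warning; a contour whose plane matches no grid slice within half a slice
thickness is assigned to the nearest slice with a warning.

On a clinical 1×1×3 mm grid the converged volume of a 25 mm sphere is
within 0.2% of the closed form. The residual error is dominated by the
slice-extrusion model itself (a stack of 3 mm slabs), not by the in-plane
rasterization, which is why refinement beyond level 1–2 changes little.

## Dose sampling and statistics

Dose is sampled by trilinear interpolation at the center of every occupied
mask voxel (mapped through a rigid transform when mask and dose live in
different frames). Voxels mapping outside the dose grid are **not** zeroed
— a silent 0 Gy would corrupt the minimum dose — but carried as an explicit
"dose-undefined" volume, excluded from statistics and reported; more than
50% undefined volume is treated as a grid mismatch and raises.

Statistics are volume-weighted by fractional occupancy: min/max over
defined samples, the median as the interpolated volume-weighted 50th
percentile (the midpoint rule, so a uniform field returns exactly its
value), and the volume at-or-above an isodose threshold. Cumulative DVHs
are computed exactly from the sorted samples (no binning error at the
edges); the uniform bin grid (default 0.1 Gy) only determines the evaluation
points. Reported values are rounded to 2 decimals; bin width and reporting
precision are deliberately decoupled.

The 80%-isodose threshold is, by default, 80% of the analyzed plan's
*prescribed* dose — base and boost plans are delivered sequentially and
analyzed separately, so each plan's own prescription is the natural
reference. Whether such a cut-off should reference the prescription or the
grid maximum is ambiguous in general; the convention is switchable
(`isodose_reference: grid_max`).

## Margin expansion and location classification

The boost volume is expanded by circumferential margins (defaults 10, 15,
20 mm) using a Euclidean distance transform in physical millimetres, so
anisotropic voxels expand correctly. Measuring distances between voxel
*centers* systematically under-reaches the expansion by a fraction of a
voxel, while measuring to the blocky voxel-cube union over-reaches (the
discretized surface bulges at corners); both bias a 20 mm ball expanded by
10 mm by 3–10% in volume. The implementation instead locates the structure
surface at the 0.5 level set of the linearly upsampled occupancy indicator
(factor 3 per axis), computes the distance transform on that fine grid, and
majority-votes back to the analysis grid. This reproduces the closed-form
dilated-ball volume within ~1% and is approximately a semigroup (10 mm
twice ≈ 20 mm once, within <1%). The expansion is forced to contain the
binarized input, so extensivity holds even for isolated voxels.

Coverage of the recurrence by each nested shell (boost, boost+1 cm,
boost+1.5 cm, boost+2 cm) is the fractional-occupancy overlap divided by
the recurrence volume; nesting guarantees these fractions are
non-decreasing, which is asserted as a property test rather than assumed.
A membership flag applies a containment threshold (default 0.95). No
clinician's notion of "within" is exactly a threshold — validation studies
show physicians calling a recurrence "in the boost" when an algorithm finds
only partial isodose coverage — so the full coverage fractions are always
reported alongside the flags, and the threshold is configurable.

**Maximal extension** beyond the boost surface is reported two ways:

- `3d`: the maximum over recurrence voxels of the Euclidean
  distance-to-boost (0 inside the boost);
- `axial`: the same maximum with the superior–inferior component ignored,
  i.e. the in-plane distance to the boost's axial projection. This mirrors
  a ruler measurement on a single representative axial slice and is
  provably ≤ the 3D value. (A per-slice 2D distance to the boost's
  cross-section in the *same* slice would instead exceed the 3D distance
  and be undefined on slices without boost, so it is not used.)

Extension is additionally resolved into the six cardinal directions (by the
dominant component of the displacement to the nearest boost surface voxel),
supporting anisotropic-margin questions such as whether dorsal margins can
be smaller than ventro-lateral ones.

## Phantom fixtures

Clinical images cannot be redistributed, so `rtrecur.phantoms` generates
complete synthetic cases: a body ellipsoid (0 HU) in air (−1000 HU) with
high-contrast internal features (spine-like bone, liver-like block,
kidneys, a bowel-gas pocket) that give the MI metric structure and break
rotational symmetry; spherical/box structures (PTV, boost, spinal cord,
recurrence); and analytic dose fields (uniform, linear gradient, spherical
falloff) on a separate, coarser dose grid. Defaults: 96×96×36 voxels at
2×2×3 mm, base plan 44.5 Gy / boost 9 Gy (the boost plan's own sequential
contribution), Gaussian HU noise σ = 10 (seeded), optional body shrinkage
emulating the pronounced weight loss seen in this population.

The follow-up CT is produced by evaluating the analytic phantom at
ground-truth-transformed coordinates — not by resampling — so it differs
from the planning CT by *exactly* the known rigid motion plus noise.
Fixtures are exported as genuine DICOM (CT series, RTSTRUCT, RTDOSE)
through the package's own writers with deterministic UIDs and fixed dates:
identical spec+seed gives bit-identical files, and the format code is
exercised rather than bypassed.

Every fixture carries machine-readable expected values: closed-form sphere
volumes, uniform-field dose statistics, and — for the boost-plus-lobe
recurrence fixtures — exact coverage fractions of every margin shell from
sphere-union/lens geometry. What the phantoms do **not** emulate: realistic
anatomy and texture, deformable anatomy changes (organ shifts, stent
placement), partial-volume and beam-hardening artifacts, and non-analytic
dose distributions. Passing tests therefore demonstrate geometric and
dosimetric correctness of the algorithms under known rigid motion, not
robustness to deformation — rigid registration is a modeling assumption of
the whole workflow, and deformable registration is explicitly out of scope.

## Problem sizes and reproducibility

Test and acceptance problem sizes (≈96³-voxel CTs, ≤32³ oracle grids, 50+
randomized classification fixtures) were chosen so every check runs
comfortably on a single CPU while keeping discretization errors well inside
the asserted tolerances. `scripts/acceptance.py --seed N --out out.json`
re-measures all headline quantities from scratch; all randomness (phantom
noise, metric sampling) derives from the given seed, and the end-to-end
pipeline is byte-identical across reruns with the same configuration.

## Known limitations

- Voxelization and classification require axis-aligned (identity
  direction) grids; oblique acquisitions must be resampled first.
- Dose-undefined handling assumes the dose grid covers most of the
  structure; severely truncated dose grids abort the analysis by design.
- The IMRT sum-plan case is detected (dose summation type) and flagged;
  decomposing a composite plan into per-plan doses is out of scope.
- Statistics use voxel-center dose sampling; near steep dose gradients the
  minimum/maximum can differ from the continuum extremes by a
  voxel-gradient product (quantified against the brute-force oracle in the
  tests).
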