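# Methods

This note documents the model, the numerical choices, and what the synthetic
fixtures do and do not establish about clinical data.

## Geometry and coordinates

Patient coordinates are millimetres. Voxel grids are 0-based with half-open
extents `[origin, origin + n·spacing)`; the centre of voxel *i* is
`origin + (i + 0.5)·spacing`. The beam frame is set by the gantry angle
(rotation about patient +y); at gantry 0 the central axis points along −z.
The virtual point source sits at SAD (default 1000 mm) upstream of the
isocenter on the axis. The source position is a convention, not a measured
effective source distance: the ray divergence it produces is the geometric
one, and it is configurable per beam.

The design grid (the SBT plane) lies in the plane through the isocenter
perpendicular to the axis, 2.5 mm spacing by default, indexed so the central
axis is the middle grid point. The grid covers the applicator projection plus
a 10 mm margin — the same band the outside-PTV extrusion operator acts on.
Field sizes are defined at the isocenter plane; only square applicators are
modelled.

## Thickness estimation

Along each grid ray, structure depths are ray-parametric: the proximal depth
is the first entry into a mask, the distal depth the last exit (fixed-step
sampling at half the smallest voxel dimension, bisection-refined to 0.01 mm).
The distal 90% isodose depth is the deepest downward crossing of the
trilinear dose along the ray, bisected to 0.05 mm; dose that stays above the
level out to the grid boundary yields "no crossing" rather than a spurious
edge crossing.

The gap between distal 90% and distal PTV is converted to bolus millimetres
with the CET line integral. Because the CET profile along a ray is piecewise
constant (one density per voxel, via the piecewise-linear HU→density table),
the integral is evaluated exactly: every voxel-boundary crossing is resolved
(Siddon-style traversal) and CET × segment length is summed. This makes the
integral exactly additive over subintervals and independent of any step-size
choice. The default table anchors water at 0 HU → 1.000, printed PLA at
160 HU → 1.119, bone at 800 HU → 1.5 and air at −1000 HU → 0.001; a clinic
table can be supplied as YAML. CET_bolus defaults to 1.119 (the density
ratio of solid printed PLA, self-consistent with the 160 HU override used at
recalculation); the slab-measured 1.13 can be configured instead.

Negative thickness is clamped at zero — bolus cannot be removed below the
skin — and the clamp count is reported. A PTV ray without an isodose
crossing is flagged and filled from its nearest valid neighbour so a single
degenerate ray does not abort a design.

## Regional modulation operators

The three smoothing operators share one Gaussian regional kernel with
smoothing factor SF ∈ {5, 10, 20} mm (low/medium/high; default 10). For each
adjusted point *p*, neighbours *q* at distance r < SF (strictly) contribute
weight `exp(−r²/2SF²)`; mode 1 omits the self term (shrinkage, for regions
whose values are unreliable), mode 2 keeps it (a convex average that
preserves constants). All updates in one application are simultaneous;
neighbour points are never modified.

Decisions that were genuinely open and the choices made:

- **Coverage smoothing annulus**: thinning must extend "somewhat" beyond the
  under-dosed projection; the annulus width is set to SF, and its neighbours
  are drawn from the under-dosed region plus the annulus, so the thinning
  bleeds outward but never beyond one smoothing length.
- **Irregularity smoothing domain**: the gradient statistic (flag cells above
  2× the mean gradient magnitude) and its neighbourhood are restricted to the
  PTV projection. Before extrusion runs, values outside the projection are
  not yet defined and would contribute an artificial cliff that dominates the
  statistic. Passes are capped at 3 to guarantee termination.
- **Margin kernel constants**: K1 is implemented as `σ·√(−2 ln 0.01)` so that
  Ker(K1) = 0.01 exactly — the property that defines K1 as "the distance over
  which the kernel rises from 0.01 to 1". The default σ is `√(E[MeV]·A[cm])`
  mm (e.g. 9 MeV, 10 cm → 9.49 mm): it increases with both energy and
  applicator size and keeps K1 commensurate with the 10 mm border; the
  alternative reading E·A (90 mm for that beam) would zero the entire border.
  σ is configurable.
- **Radial constructions**: both the margin operator's inner-boundary point
  *m* and the extrusion operator's boundary point *n* are found by walking
  the segment from the point toward the central-axis projection at quarter-
  cell steps. If the walk misses (central axis outside the projection, or a
  concave projection), the nearest boundary point is used and a warning is
  logged; the radial definition assumes a star-shaped projection, which all
  fixture PTVs satisfy.

Operator order is fixed: hot spot → coverage → irregularity → margin →
extrusion.

## Dose engine

The built-in engine is a broad-beam model, present so that the iteration loop
has a deterministic, monotone, heterogeneity-aware dose source at desk scale;
it is not a Monte Carlo replacement, and the adapter accepts an external
RTDOSE per iteration for clinical use. Per energy E (MeV): R50 = E/2.33 cm,
Rp = E/2 cm, z_max = 0.6·R50; 85% surface dose rising parabolically to 100 at
z_max; beyond z_max a logistic falloff rescaled to 100 at z_max and calibrated
(by root finding, tolerance 1e-10) so dose(R50) = 50, atop a 2% bremsstrahlung
tail. Each voxel takes the model value at its water-equivalent depth along
its ray (bolus CET path + cumulative tissue CET at 0.5 mm steps), times
error-function field edges with penumbra σ(z) = 2 mm + 0.05·z. Lateral
scatter from bolus-shape gradients is not transported; an optional
thickness-gradient kernel (Gaussian-blurred neighbour excess, 1%/mm, clipped
to ±20–30%) can mimic the midline hot spots that strongly modulated bolus
produces, for exercising the hot-spot operator.

What the surrogate does not emulate: oblique-incidence corrections, output
factors, large-angle scatter, backscatter at interfaces. Convergence results
on the fixtures therefore demonstrate the correctness of the design loop
given a physically plausible engine, not clinical dosimetric accuracy.

## Calibration

The falloff shift between an open-water depth-dose curve and a slab curve is
found by scanning a ±10 mm shift range at 0.05 mm steps, minimizing the sum
of squared differences over the 20–80% falloff window (buildup regions differ
in shape, not only in shift), with parabolic refinement of the discrete
minimum; a minimum at the search boundary raises a non-convergence error.
Positive shift = slab curve shallower, matching shift = (CET − 1)·t for
CET > 1. The CET estimate is 1 plus the least-squares slope of shift vs
thickness through the origin, with a residual-based uncertainty.

## Mesh generation

The inner sheet samples the ray–skin entry points, the outer sheet is
displaced along each diverging ray by the local thickness, and a skirt closes
the boundary; the solid is watertight by construction and verified
edge-manifold. A 0.05 mm thickness floor over the meshed footprint (far below
any printable layer height) prevents degenerate sheets; an all-zero map
yields no solid. Mesh resolution equals the design grid (optional 2×
supersampling). Voxelization reuses the same fan geometry (a voxel is bolus
iff its ray parameter lies between the sheets), with the 160 HU override of
printed PLA recorded for recalculation. Print-profile metadata (layer height
0.1/0.2/0.3 mm, 100% linear infill) goes into a sidecar YAML and is not acted
upon.

## Iteration loop and stopping

Acceptability is judged on bolus plans only: the initial no-bolus plan is
constructed to cover the PTV, so at least one design pass always runs. The
loop stops when V90 ≥ 98% and Dmax ≤ 110% (both configurable), when V90 fails
to improve for two consecutive iterations, or at the iteration cap (5).
Thickness is capped at 40 mm with a warning (printability). Runs are
deterministic given configuration and seeds.

## Synthetic fixtures and problem sizes

The phantom generator reproduces the desk-scale test geometries: a
20×20×20 cm³ water cube with a wedge PTV (distal ramp 20→40 mm) and bone/air
slabs distal to it, and curved-surface phantoms (sinusoidal or spherical-cap
entrance) with a surface-following PTV. HU values: water 0, bone +800, air
−1000, PLA +160; optional seeded Gaussian HU noise (σ = 10) is off by
default so exact oracles remain exact. Unit tests use 1 mm voxels on ~10 cm
phantoms; pipeline and convergence tests use 2.5 mm voxels on the full 20 cm
cube (80³ voxels, 49×49 design rays), where a full design runs in seconds.
The wedge PTV dimensions and slab sizes are this package's choices of a
representative geometry, documented here, not prescribed values.

What passing tests show: the estimator, operators, calibration and mesh
pipeline are internally correct against independent oracles, and the loop
converges on idealized geometries. What they do not show: performance on
real CT anatomy, real printer tolerances, or agreement with a commissioned
dose engine — those require the external-dose adapter and measurement.
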