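# Methods

## The quantity being computed

An isodose volume at level L is the superlevel set {dose ≥ L}; its boundary
is the isodose surface.  Because superlevel sets are nested, the average
distance between two isodose surfaces is well estimated by the volume
between them divided by their mean area,

    DGI = (V_L − V_H) / (½(S_L + S_H)),

the coarea estimate of shell thickness.  For concentric spheres of radius
r and r + d the estimate has the closed form d·[(r+d)+d²/3r]/[(r+d)+d²/2r];
for nested cubes (edge a, gap d) it is d·[(a+2d)+4d²/3a]/[(a+2d)+4d²/2a].
The relative error 1 − DGI/d is 0.0055 at 2r = 10 mm, d = 1 mm and 0.0006
at d = 0.3 mm, vanishing as d → 0.  A point worth noting: when a = 2r the
cube expression's numerator and denominator are each exactly twice the
sphere's, so the two relative errors coincide *exactly*, not merely to
leading order.  Since the estimator is exact in the small-gap limit, the
calculation interval should not exceed 1% (or 1 Gy).

The differential curve (dDGC) applies the estimator to each consecutive
level pair on a lattice of levels anchored at the reference dose; the
cumulative curve (cDGC) sums the differential values from the reference
dose downward, so cDGI(reference) = 0 exactly and each point is the mean
distance from the reference isodose surface.  Normalizing the dDGC by the
step size puts curves from different steps on a common mm-per-% scale.

## Surface extraction

Isodose surfaces are extracted directly from the dose grid by marching
cubes with linear interpolation along voxel edges
(`skimage.measure.marching_cubes`, `gradient_direction="ascent"` so
normals point outward and the divergence-theorem volume is positive).
The grid is padded by one voxel below the level before extraction, so
every produced mesh is watertight by construction; disconnected isodose
components are pooled into a single V, S per level because the estimator
is defined on totals.  Surface area is the half-cross-product sum and
volume the signed tetrahedron sum — exact for the triangulation; `trimesh`
is used only as an independent cross-check in the tests and for STL/PLY
export.

The evaluation domain is the body eroded by 3 mm (exact Euclidean distance
transform, anisotropic-spacing aware), which removes build-up and skin
artefacts.  A level whose surface reaches the domain boundary cannot be
capped without corrupting its area, so the level table is truncated there:
levels run from just below the maximum dose down to the last level whose
surface is strictly interior, and the truncation dose is logged.  Input
grids coarser than 1 mm are resampled trilinearly to 1 mm by default,
matching the resolution the method was characterised at.

Surfaces of *binary masks* (used by the verification fixtures) need more
care: marching cubes on 0/1 data or on the raw voxel-centre distance field
produces facets that inflate area by ~8–9%.  `mask_surface` therefore
(1) meshes the signed Euclidean distance field, (2) smooths it with a
0.7-voxel Gaussian and cancels the smoothing-induced inward drift with the
Laplacian curvature correction F = d_s − (σ²/2)∇²d_s, which is exact for a
radial distance field, and (3) calibrates the extraction level by bisection
so the mesh volume equals the mask's voxel-count volume.  On voxelized
spheres of radius 5–15 mm at 1-mm spacing this keeps volumes within 2% and
areas within 3% of the analytic values, tightening as the spacing halves.

## Synthetic phantoms

No reproducible dose engine exists for clinical arc plans, so verification
uses constructions whose isodose geometry is closed-form:

* **Radial SRS field** — D(r) = D_ref · min(core, (R_t/r)^k) around a
  spherical target.  Defaults: R_t = 15 mm (3-cm target), D_ref = 15 Gy
  prescribed at the target surface, k = 2 (inverse-square far field, which
  also reproduces the benchmark plan's cDGI_50% scale: 6.21 mm here vs
  5.98 mm for the plan), core cap 125%, body radius 50 mm, 1-mm grid.
  Every isodose at fraction f of the reference (below the cap) is a sphere
  of radius R_t·f^(−1/k).  Optional seeded multiplicative noise is off by
  default so the geometry stays analytic.
* **Multi-layer structures** — a base shape (sphere, cube, or a seeded
  irregular blob: a sphere perturbed by spherical harmonics of degree 2–4,
  amplitude capped at 25% so it stays star-shaped, rescaled to the target
  volume) expanded uniformly at a regular interval.  The ground truth for
  any layer pair is the interval itself.  Layer surfaces are level sets of
  the exact signed distance to the base surface (closed form for
  sphere/cube; nearest of ~4·10⁵ analytically placed surface samples for
  the blob, with a thinned sample cloud for the far band where its
  ≤0.01 mm error is negligible and shared between neighbouring offsets).
  Layer *masks* threshold the same field at voxel centres, which keeps
  sub-voxel intervals (0.3 mm on a 0.5-mm grid) meaningful — a binary
  mask alone cannot represent them, which is why `uniform_expand` of a
  mask is reserved for intervals at or above the voxel size.
* **Renormalization** — rescaling the dose so a chosen isodose level
  receives the prescription is a global scalar multiplication; isodose
  surfaces are relabelled but not moved, which the tests assert.

What these phantoms do *not* emulate: multileaf-collimator penumbra
anisotropy, scatter tails, multi-target interference, or noise textures of
a real dose engine.  Passing tests demonstrate the correctness of the
geometry and index arithmetic under known conditions, not the dosimetric
realism of any planning system.

## Bundled benchmarks and their precision

Two published benchmark tables are bundled as data: the 14-layer uniform-
expansion structure (surface areas, volumes and DGI at 1/2/3-mm gaps) and
the isodose table of a 3-arc SRS plan (3-cm target, 15 Gy, 1% interval).
Both are inputs to the index arithmetic, not meshing fixtures.  Their V, S
columns are printed to 10⁻³, and the published DGI quotients were computed
from unrounded values; propagating the printed rounding moves the sixth
decimal by a few units, so agreement is asserted to 3·10⁻⁶ — the printed-
precision radius, not a fitted tolerance.  The benchmark's cumulative
column accumulates its *rounded* differential column (summing unrounded
values gives 1.15 rather than the printed 1.13 at the 90% level), and the
reproduction follows that convention.

## Numerical choices and edge cases

* Levels sit on a lattice anchored at the reference dose; in percent scale
  the percent value is carried exactly (no Gy round trip), so CSV output
  round-trips bit-exactly.
* All arithmetic is double precision; 2-decimal half-up rounding is applied
  only at report time, matching the benchmark tables' presentation.
* Adjacent levels with equal volumes (flat dose regions, e.g. an idealized
  hot core) report dDGI = 0 with a warning instead of failing the strict
  nesting precondition.
* D100% (alternative reference) is the largest dose covering 100% of the
  PTV in its voxel-counting DVH (bin width 0.1% of the prescription),
  linearly interpolated between bins.
* GI and R50% use pooled isodose volumes and the voxel-count PTV volume.
* Step-size invariance of the normalized dDGC holds where the fall-off is
  smooth relative to the step.  It is evaluated on the 60–112% window of
  the radial phantom: below ~52% the curvature of a k = 2 profile alone
  pushes a 4% step outside a 5% band (the same reason steps ≤1% are
  recommended), and within a few voxel-equivalents of the artificial core
  plateau the discrete surface placement is ill-conditioned — a modelling
  artefact with no analogue in a real plan's smooth dose peak.  The
  cumulative curve is step-invariant everywhere because its sum telescopes.

## Problem sizes

Default verification runs use 0.5-mm grids of ~110³ voxels for the
multi-layer fixtures and 1-mm grids of ~107³ voxels for the radial plans;
the full suite and the acceptance script each complete in a few minutes on
one CPU.

## Known limitations

The DGC is directionless (an average over the whole shell); directional
variants via sector volumes of interest are out of scope.  DICOM RTSTRUCT
contours are not parsed — masks must arrive as volumes.  Mask-derived
surface accuracy degrades for structures under ~10 voxels across.  GI/R50%
require the 50% isodose to be closed inside the cropped body, otherwise
they are reported as null with a warning.
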