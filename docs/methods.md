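# Methods

`nephroplan` predicts, from a segmented delay-phase CT, whether resecting a
renal tumor with a given surgical margin would transect ("open") the urinary
collecting system — the event that forces intraoperative suturing to prevent
postoperative urine leakage — and where that opening would be. This note
documents the models, parameters, numerical choices, and limitations.

## Coordinate model

Volumes are axis-aligned 3D grids. Voxel indices are 0-based `(i, j, k)`;
`spacing` is mm per voxel along each array axis; `origin` is the world-mm
position of the **center** of voxel `(0,0,0)`, so `world = origin + index *
spacing` and voxel centers sit at integer indices. NIfTI images with oblique
(rotated) affines are rejected rather than silently reduced: every mm
distance downstream assumes an axis-aligned grid. Masks are written as 0/1
`uint8` NIfTI for portability.

## Segmentation

Three structures, three methods, chosen to match how each structure presents
in delay-phase contrast CT.

**Kidney — graph cut.** Binary labeling by exact s–t min-cut on the voxel
graph (solved with igraph's max-flow). The energy is

    E(L) = λ · Σ_v  −log p_{L(v)}(I_v)
         + Σ_{p~q, L(p)≠L(q)}  exp(−(I_p − I_q)² / 2σ²) / (1 + |p−q|_mm)

with hard constraints at user scribbles. Class likelihoods `p_fg`, `p_bg`
are Gaussian kernel density estimates (Silverman bandwidth) of the scribble
intensities — the minimal model consistent with "inside and outside control
points" as the only user input. Parameters:

| parameter | default | meaning |
|---|---|---|
| `lambda_region` | 0.1 | weight of the likelihood (region) term, dimensionless; the negative-log-KDE unary is tens per voxel while boundary weights are at most ~0.5 per face, so 0.1 keeps the cut pinned to intensity edges instead of annexing shells of extreme-noise voxels |
| `sigma_boundary` | estimated | intensity scale of a "real" edge, CT units; default is the median absolute intensity step between neighbouring voxels of the volume — a robust scale that adapts to noise level |
| `neighborhood` | 6 | 6 or 26 voxel neighbourhood (full 3D in either case) |

Min cuts need not be unique; the contract is the energy value and the hard
constraints, not one particular labeling.

**Urinary tract — seeded region growing.** The collecting system is
contrast-bright, so the grown region is the connected component (default
6-connectivity, which resists diagonal leakage through thin tract walls) of
`{voxel : CT > r}` containing each seed, with `r` a per-patient threshold,
clinically in [350, 420]. The comparison is strict (`>` r). Seeds at or
below `r` are an error naming the offending seed, since they indicate a
mis-placed seed or a wrong threshold. The operation is idempotent and
monotone non-increasing in `r`; implemented as threshold + connected-component
labeling, which is the fixed point of front evolution restricted to
supra-threshold voxels.

**Tumor — contour-based implicit surface.** Tumors often lack a
high-contrast boundary, so the user draws closed planar contours on a few
slices and a smooth closed surface is interpolated through them. A signed
scalar field (negative inside) is built by radial-basis interpolation with a
triharmonic (cubic, φ(r) = r³) kernel and a linear polynomial term:
value 0 at every contour vertex, ±h at points offset along outward normals,
with h the mean in-plane voxel spacing. The offset normals are **tilted out
of plane**: the out-of-plane slope at each vertex is estimated from the
nearest vertex of the adjacent contour on each side (a secant estimate of
the surface tangent), and the offset direction is rotated perpendicular to
it. With purely in-plane normals the field has no information that the
surface closes beyond the extreme contours and bulges past them (≈ +6%
volume on a sphere sampled by three contours); the tilt reduces this to
≈ +2% volume and 0.16 mm RMS surface error. `smoothness` (default 0 =
exact interpolation) is passed through as the RBF smoothing parameter;
`tol_fit` (default 0.25 mm, a quarter of typical in-plane spacing) is the
acceptance tolerance for reproducing input vertices. The segmentation mask
is `{voxel centers : field < 0}`.

## Geometry

**Distance fields.** Distances are voxel-center to voxel-center: the exact
anisotropic Euclidean distance transform (scipy) of the source-mask
complement, in mm. This is well-defined and oracle-checkable (brute-force
all-pairs agreement to 1e-9 mm); it is *not* sub-voxel surface distance —
see "Discretization bias" below.

**Surfaces.** Marching cubes at iso-level 0.5 on the 0/1 mask, one zero
layer of padding first so border-touching structures still close. Optional
Laplacian smoothing refuses to proceed if it would change enclosed volume by
more than 2%; the default for plain mesh extraction is 0 iterations so
geometric tests are exact. Mesh volume is the divergence-theorem sum
(orientation-independent), defined only for watertight meshes (every edge
shared by exactly two faces). CT values are attached to vertices by
trilinear interpolation (out-of-grid vertices clamped with a warning) —
a per-vertex stand-in for texture-mapping CT slices onto the cut surface.

## Resection planning

For margin m, the **removed region** is every voxel of kidney ∪ tumor whose
center lies within m mm (closed ball, so boundary cases count as removed) of
the nearest tumor voxel center. The domain is the *union* of kidney and
tumor masks so that segmentation disagreement at the tumor rim can never
exclude tumor tissue — a safety-side convention. The distance field is
computed once per study and thresholded per margin.

The **resection surface** is the interface between removed tissue and
remnant kidney: the marching-cubes surface of the removed region, lightly
smoothed (3 Laplacian iterations; staircase artifacts otherwise inflate the
area by ≈ 8%), with capsule faces removed. Capsule faces are identified on
the unsmoothed geometry: the iso-surface runs midway between voxel centers,
so capsule-face centroids interpolate to ≈ 0.5 voxel of interior depth while
interface faces lie at least a full margin deeper; the classification
threshold is 0.75 of the smallest voxel step.

The tract is **open** at margin m iff the removed region and the tract mask
share at least one voxel — actual transection, not proximity, matching the
intraoperative criterion (a transected collecting system needs sutures).
The opening is reported as the world-mm centroid of the shared voxels plus
their maximum pairwise extent (exact up to 5000 voxels, convex-hull-reduced
beyond). Open status is monotone in the margin by construction; the report
carries the smallest scheduled margin that opens the tract
(`min_opening_margin`, default schedule 1–5 mm every 1 mm) and the
continuous minimum tumor-to-tract distance, phrased clinically as
"Open with N mm margin" / "Not open with 5 mm margin". The continuous
distance is reported because the schedule answer alone hides how close a
call is.

### Discretization bias

The voxel-center metric can only *overestimate* the true surface-to-surface
gap (voxel centers lie strictly inside their shapes), by at most one voxel
diagonal (1.39 mm at 0.8 mm spacing; measured on 50 randomized phantoms:
mean +0.34 mm, max +1.26 mm). Consequently the predicted opening margin can
exceed the analytic ceiling of the gap by one (rarely two) 1-mm steps, and
predictions err toward "opens at a larger margin than the true geometry
suggests". The acceptance study therefore scores predictions within the
one-voxel-diagonal band `[ceil(gap), ceil(gap + diagonal)]` (100% of 50
phantoms) and reports strict ceil-agreement separately (≈ 70–80%). Users
needing sub-voxel margins should resample to finer spacing; the bias scales
linearly with voxel size.

## Phantoms

The phantom generator emulates exactly the contrast pattern the pipeline
exploits: a kidney ellipsoid of parenchyma (150 CT units) on background 0,
an embedded hypodense tumor sphere (60), and a contrast-filled tubular tract
(500 — above the 420 upper end of the clinical threshold range, so any valid
`r` segments it), plus Gaussian noise (default sd 15). Defaults: 0.8 mm
isotropic spacing, kidney semi-axes (50, 30, 25) mm, tumor radius 12 mm, a
3-segment tract centerline of tube radius 2 mm whose middle segment realizes
a surface gap of exactly 2.5 mm from the tumor. Tumor/parenchyma contrast is
required to be ≥ 3× the noise sd. Masks are voxelized as "center inside the
analytic shape"; the tumor-tract gap is known in closed form (the closest
point of a capsule to an external sphere lies along the point-to-segment
line), verified in tests against numeric minimization and dense surface
sampling. One `rng_seed` drives noise and annotation sampling, so a spec
reproduces bit-identical volumes.

Randomized phantoms (`random_phantom_spec`) draw tumor radius (8–13 mm),
tumor position, and the tract approach direction at random, then place a
straight tube at an exactly known gap (uniform 0.5–7 mm by default) — the
basis of the margin-prediction study.

What phantoms do **not** model: CT texture and reconstruction artifacts,
partial-volume averaging at boundaries, respiratory deformation, anatomical
variation of the collecting system, and perinephric structures. Passing
tests demonstrate correctness of the geometry and the segmentation
machinery under the stated intensity model, not clinical performance on
patient CT.

## Reproducibility

All stochastic steps take explicit seeds. Pipeline runs with identical
config and seed produce byte-identical `report.json` (floats rounded to
1e-6, sorted keys, no timestamps); `provenance.json` records the config
echo, package version and SHA-256 checksums of all inputs. The report
schema is shipped as pydantic models (`nephroplan.pipeline.ReportModel`;
`nephroplan config --schema` prints JSON Schema).

## Problem sizes

Default study sizes keep a full run light: the randomized margin study uses
50 phantoms on 128³ grids (≈ 1 s per phantom for generation + planning
without surface extraction); segmentation quality checks use 40³–88×72×64
grids. All tests and the acceptance study complete in a few minutes on one
CPU.

## Known limitations

- Margins are measured to the segmented (contrast-filled) tract lumen, not
  the tract wall; wall thickness is not modelled.
- The opening "position" is a centroid + extent + highlighted submesh, not a
  rendered comparison with the operative view.
- Graph-cut energy parameters are not auto-tuned per patient beyond the
  sigma estimate; heavily textured volumes may need manual `lambda`/`sigma`.
- The contour-surface method assumes contours sample a single closed,
  star-shaped-ish object; topology changes (bifid tumors) are out of scope.
- No vessel planning, nephrometry scoring, or intraoperative deformation.
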