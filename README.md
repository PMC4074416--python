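# nephroplan

Virtual resection-plane planning for laparoscopic partial nephrectomy from
3D CT.

## The problem

In partial nephrectomy a renal tumor is resected with a rim of healthy
parenchyma (the *surgical margin*). If the resection transects the urinary
collecting system — an **open urinary tract** — the defect must be sutured
intraoperatively to prevent postoperative urine leakage. Whether a given
margin opens the tract, and where, is valuable preoperative information that
is hard to infer from 2D CT slices, especially for the restricted view of
laparoscopy.

`nephroplan` answers this from a delay-phase contrast CT (in which excreted
contrast fills the collecting system):

1. **Segment** kidney, urinary tract and tumor from the volume plus light
   user annotations — graph cut (min-cut on the voxel graph) from
   foreground/background scribbles for the kidney; seeded region growing
   restricted to voxels with CT value > *r* (clinically *r* ∈ [350, 420])
   for the contrast-bright tract; a smooth implicit surface interpolated
   through hand-drawn planar contours (triharmonic RBF) for the tumor.
2. **Plan** resections at a schedule of margins *m* = 1…5 mm: the removed
   region is every kidney-or-tumor voxel within *m* mm of the tumor
   (anisotropic Euclidean distance transform, closed ball); the resection
   surface is the removed/remnant interface extracted by marching cubes
   (capsule faces excluded), with CT values sampled onto its vertices.
3. **Predict the opening**: the tract is open at margin *m* iff the removed
   region intersects the tract mask. The report gives the per-margin status,
   the smallest opening margin, the opening centroid and extent in mm, and
   the continuous minimum tumor-to-tract distance, phrased as
   `"Open with N mm margin"` or `"Not open with 5 mm margin"`.

No patient data is required: the `phantom` module synthesizes delay-phase-like
CT volumes (kidney ellipsoid, embedded tumor sphere, bright tubular tract)
with *exactly* known geometry, so every stage is testable against closed-form
answers. See `docs/methods.md` for the models, parameters and limitations.

## Worked example

Generate a phantom whose tumor-to-tract surface gap is exactly 2.5 mm, then
plan resections at 1–5 mm margins using the ground-truth masks:

```bash
$ nephroplan phantom --out-dir fx --seed 7
phantom written to fx (analytic tumor-tract gap 2.500 mm)

$ nephroplan plan --ct fx/ct.nii.gz --kidney fx/kidney_truth.nii.gz \
    --tumor fx/tumor_truth.nii.gz --tract fx/tract_truth.nii.gz --out-dir plans
Open with 4 mm margin
```

`plans/report.json` then contains

```json
{
  "status_text": "Open with 4 mm margin",
  "min_opening_margin_mm": 4.0,
  "min_tract_distance_mm": 3.2,
  "per_margin": [ {"margin_mm": 3.0, "open": false, ...}, ... ]
}
```

Reading: the smallest scheduled margin at which the resection would enter
the collecting system is 4 mm; resecting at ≤ 3 mm leaves the tract intact.
The measured voxel-center distance (3.2 mm) exceeds the analytic 2.5 mm gap
because grid distances are voxel-center to voxel-center — they overestimate
the true surface gap by up to one voxel diagonal (1.39 mm at 0.8 mm
spacing), so predictions err toward caution; `min_tract_distance_mm` shows
how close the call is (see `docs/methods.md`, "Discretization bias").

Alongside the report, the output directory holds the per-margin removed
regions (NIfTI), the resection surfaces (PLY with `ct_value` and `opening`
vertex properties), a `provenance.json` (config echo, version, input
checksums) and a run log.

Segmenting from annotations instead of ground-truth masks works the same way
(`fx/` also contains generated scribbles, seeds and contours):

```bash
$ nephroplan segment tract --volume fx/ct.nii.gz \
    --annotations fx/tract_seeds.json --out-mask tract.nii.gz --r 385
tract: 1121 voxels (0.6 cm3) -> tract.nii.gz
```

or end-to-end via a config file: `nephroplan run --config config.json`.
`nephroplan config --defaults` prints every default parameter.

### Annotation formats

Plain JSON with a `format_version` field:

```json
{"format_version": "1.0",
 "scribbles": {"foreground": [[i,j,k], ...], "background": [[i,j,k], ...]}}
{"format_version": "1.0", "seeds": [[i,j,k], ...], "threshold": 385.0}
{"format_version": "1.0",
 "contours": [{"plane_axis": 2, "plane_index": 31, "points": [[u,v], ...]}]}
```

Indices are 0-based voxel coordinates; contour points are continuous
in-plane voxel coordinates on the two remaining axes in increasing order.

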