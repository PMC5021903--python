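# Methods

This note documents the models, numerical choices and limitations of
`foveafinder`: what each stage assumes, which parameters matter, what the
synthetic phantoms do and do not emulate, and where the design was
genuinely open.

## Scope and coordinate conventions

A volume is a non-negative intensity grid indexed `(x, y, z)`: `x` is the
fast lateral axis within a B-scan, `y` the slow axis across B-scans, `z`
axial depth increasing away from the vitreous. Physical positions refer
to voxel centres, `(i + 0.5) · spacing`; spacings derive from the voxel
counts and a physical field of view (default 6 × 6 × 2 mm). This
voxel-centre convention is a package decision — device exports do not
state one — and anyone comparing against reading-centre annotations
referenced to voxel corners should expect a systematic half-voxel offset.

Surface *elevation* is defined once as `E(x, y) = extent_z − z_ILM(x, y)`
so that retina pushed toward the vitreous has larger elevation; all shape
analysis uses this quantity.

## Preprocessing

**Axial motion correction.** Microsaccades displace whole B-scans
axially. Each B-scan is summarised by its mean A-scan profile; adjacent
profiles are aligned by maximising cross-correlation over integer shifts,
the pairwise shifts are accumulated along the slow axis and re-centred to
zero median so the volume as a whole is not translated. Assumption: the
retina is the dominant intensity structure of every B-scan; an all-dark
B-scan keeps a zero shift and is logged. Sub-voxel and lateral motion are
out of scope.

**Tilt correction.** The retinal band position is traced per column
(Otsu threshold after light smoothing) and a Theil–Sen line is fitted
**to the peripheral quarters of the B-scan only**: tilt is a global
acquisition artefact, whereas the central columns carry genuine macular
curvature (dome, pit) that a whole-width fit absorbs into its slope and
then wrongly shears away — this failure mode was observed directly on
edema phantoms. Slopes below 0.005 voxels z per voxel x are ignored; the
shear uses integer per-column offsets about the B-scan centre. Tilt is
estimated per B-scan rather than as one global plane; the two choices
coincide on rigid tilt and the per-B-scan form also absorbs slow slope
drift.

**Speckle denoising.** OCT speckle is multiplicative, so each B-scan is
log-transformed, filtered with fast patch-based non-local means
(patch 3, search radius 5, strength `h = 0.8 · σ̂ ·` `denoise.strength`
with `σ̂` from the median absolute deviation of horizontal first
differences), and exponentiated back. The contract downstream stages
rely on: flat-region variance reduced by at least half, planted edges
moved at most one voxel. Both are asserted in tests. A 3×3 median variant
(`denoise.method = "median"`) and an identity (`"none"`) are available.

**Foveal masking.** An ellipse of full axes `nx/2 × ny/2` (i.e.
semi-axes a quarter of each dimension) centred at the scan centre,
propagated through depth into a cylinder. "Size X/2" is read as full
axis length: a semi-axis of X/2 would cover the whole scan and make the
mask pointless. The scan centre stands in for the population-mean fovea
position, which in trained-grader data lies within roughly 80–140 µm of
it — small against the mask's 1.5 mm semi-axis.

## Kernel graph-cut segmentation

Each B-scan is partitioned into tissue and background by minimising

    E(l) = Σ_p (1 − K(I_p, μ_{l_p})) + λ Σ_{(p,q)∈N4} [l_p ≠ l_q]

with `K` a radial-basis kernel on intensity whose bandwidth is
`1.4826 · MAD` of the B-scan (floor 0.02), region representatives `μ_l`
updated by the kernel-weighted fixed point, and the binary cut solved
*exactly* by integer max-flow (capacities scaled by 10⁴;
`scipy.sparse.csgraph.maximum_flow`, partition recovered by BFS on the
positive residual graph). Representative update and cut alternate until
labels stabilise (≤ 10 iterations). Exactness of the single cut is
verified against exhaustive enumeration on random small instances.

ILM delineation takes, per column, the shallowest tissue voxel, after
removing in-plane tissue components smaller than 30 px (floaters above
the retina), interpolates single-column gaps, and marks empty columns
invalid. A *relaxed* boundary weight — `segment.relax_factor = 0.25`
of the default λ = 0.6 — is used here so the cut follows fine surface
detail instead of smoothing it away.

## Two-surface search for the NFD branch

For near-normal volumes the ILM and the RNFL posterior boundary are
found per B-scan by dynamic programming: a single-valued surface `z(x)`
minimising a per-column cost under the hard bound `|z(x) − z(x−1)| ≤
s_max` (default 2 voxels). The DP optimum is verified against exhaustive
path enumeration on toy instances.

* **ILM cost**: negative axial intensity gradient (dark→bright), after
  lateral Gaussian smoothing (σ = 2 columns).
* **RNFL-bottom cost**: a *box-filtered* derivative,
  `D(z) = mean(I[z:z+w]) − mean(I[z−w:z])` with `w = 8` voxels,
  clipped to reward only bright→dark transitions, plus a small bias
  (2·10⁻³ per voxel of separation) pulling the surface toward the ILM.
  Rationale: the RNFL/inner-retina edge is a low-contrast step; a
  per-voxel central difference is indistinguishable from residual
  speckle, while the box window averages `w` voxels each side and
  recovers the edge reliably. Where no posterior edge exists — the
  foveal pit, where the RNFL vanishes — nothing opposes the bias and the
  surface collapses onto the ILM, which is exactly what makes the
  thickness map reach zero at the fovea. Two guards are needed: the
  region above the ILM is padded with the ILM intensity so the vitreous
  cannot leak into the upper window, and the search corridor
  (`max_rnfl_um = 160`) is additionally capped `w + 2` voxels above the
  last bright voxel of each column (an RPE proxy), because the far
  stronger posterior boundary otherwise captures the window wherever a
  deep pit brings it within reach.

Consequences worth knowing: thickness is measured reliably up to the
corridor depth and the box window blurs layers thinner than `w` voxels,
so the zero-thickness disk is somewhat wider than the anatomical one —
harmless for a centre-of-mass landmark, and the surface-recovery test
asserts 1-voxel RMS only where the planted layer is thicker than 70 µm.

## IRF extraction

Candidate fluid regions are voxels between the ILM and the last bright
voxel per column, darker than the two-class (Otsu) split of the
intra-retinal intensities **and** with component mean below half the
tissue mean — fluid is hyporeflective, and without the second condition
the darker of two ordinary tissue layers qualifies. Components (3D,
6-connectivity) smaller than `min_volume_vox = 50` are dropped; the rest
are ranked darkest first and the darkest region whose centroid lies
inside the foveal mask feeds detection.

## Appearance classification

A *peak* is a data point strictly larger than both neighbours; plateau
runs count once, at their centre, when strictly above both flanks. On
each B-scan the masked elevation profile is median-filtered (3 points)
and box-smoothed (5 columns), and peaks must reach a prominence of 20 µm
(`classify.min_prominence_um`) to count — the strict definition is kept
as the primitive, the prominence gate protects it from residual surface
noise of a few voxels. Shapes, in decision order: TWO_PEAK (≥ 2
prominent peaks, global maximum among them), SINGLE_PEAK (exactly one
prominent peak at the global maximum, profile unimodal after 3-point
median smoothing), DEPRESSION (the central minimum flanked on both sides
by ≥ 20 µm higher elevation), else FLAT.

A shape classifies the volume only when it persists across ≥ 150 µm of
contiguous slow axis, counted as slab coverage `k · dy` rather than span
`(k−1) · dy`, so a single B-scan of a wide-pitch raster can satisfy the
criterion on its own — the point of a physical distance is cross-vendor
comparability. Volume-level decision order, most specific first:
(1) NFD if the thickness map holds a point at or below the
zero-thickness tolerance (default one axial voxel) inside the mask *and*
DEPRESSION is contiguous; (2) MFD if TWO_PEAK is contiguous;
(3) AFD if SINGLE_PEAK is contiguous; (4) otherwise AFD with a
low-confidence flag — the AFD branch is the most generally applicable
detector and a batch pipeline must emit a position; the flag lets
evaluations exclude such cases.

## Position detection

**NFD**: centre of mass (unweighted mean) of all masked points with
thickness at or below tolerance; candidate count is the set size; z is
the ILM height at the nearest valid grid point.

**MFD/AFD**: per B-scan, all pairwise Euclidean distances between that
B-scan's ILM points and the IRF boundary points; exact zeros are
discarded as anatomically impossible contact. The global minimum over
B-scans selects the landmark; B-scans whose minima agree within
`0.5 · dz` (floating-point "identical") contribute their argmin points
to a centre of mass. If no fluid region survives extraction, the global
ILM elevation maximum is returned, flagged low-confidence with
provenance `ilm-minimum-fallback` — a package decision for a case the
detection model does not cover.

The whole chain is deterministic: a fixed volume and configuration yield
a bit-identical result.

## Synthetic phantoms

The generator emulates what the pipeline consumes: a bright retinal band
(0.70) with a brighter nerve fiber layer (0.85) over a dark vitreous
(0.05) and sub-RPE space (0.20), hyporeflective cysts (0.10) — contrast
realism, not radiometric claims — plus multiplicative gamma speckle,
per-B-scan integer jitter, and tilt shear. Geometry:

* the pit is a difference-of-Gaussians dent (centre depth 120–180 µm,
  radius 650–850 µm for NFD, i.e. ~1.5 mm diameter; the DoG's wide lobe
  adds the slight rim of real foveae);
* the edema dome is a **flat-topped super-Gaussian**
  `H · exp(−(r/σ)⁴/2)` (H 220–280 µm, σ 1100–1300 µm): cystoid edema
  lifts a broad plateau, and on a plain Gaussian dome the dome's own
  curvature cancels a residual depression of realistic size;
* the MFD residual pit is attenuated to 40% depth and is smaller and
  sharper than a normal pit (radius 350–500 µm), matching the clinical
  description of a "minor" depression and surviving on the plateau;
* the MFD/AFD cyst sits directly beneath the planted fovea with its top
  a 50–80 µm gap below the ILM, lateral semi-axes chosen (MFD
  800–1000 µm, AFD 420–520 µm) so the cyst surface curves away from the
  ILM faster than the dome does: the geometric minimum ILM–cyst gap is
  then attained at the planted fovea by construction, verified in tests
  by brute force against a densely sampled parametric ellipsoid;
* the planted fovea is jittered up to 500 µm from the scan centre;
  RNFL thickness follows `t_max (1 − exp(−r²/2σ_r²))` (t_max
  100–140 µm, σ_r 500 µm), exactly zero at the fovea for NFD and floored
  at 40 µm otherwise.

Noise levels are fixed study conditions: `"none"` (clean) and
`"default"` — speckle σ = 0.5 (fully developed speckle contrast), jitter
up to 8 voxels, tilt up to ±0.03 z-voxels per x-voxel.

What the phantoms do **not** emulate: vessel shadows, signal rolloff
with depth, acquisition dropout, subretinal fluid and pigment-epithelial
detachment, real layer multiplicity, or grader subjectivity in the
ground truth. Passing the ensemble criteria therefore demonstrates the
pipeline's internal correctness and noise robustness under this model,
not clinical-grade performance; the phantom localisation errors
(means of roughly 45 µm clean and 65–120 µm at default noise on the
reduced grid) sit *below* the 159.5–262 µm reported against human
annotations on clinical data, as expected for an easier, noise-controlled
task with exact ground truth.

Ensemble studies use a reduced 128×49×256 grid over the same 6×6×2 mm
field (Spectralis-like B-scan pitch, ~47 µm lateral and ~7.8 µm axial
spacing), a deliberate problem-size choice that keeps the 120-phantom
recovery study to a few minutes while preserving every geometric
property the criteria exercise.

## Evaluation statistics

Accuracy is `100 · trace/total` of a 3×3 confusion matrix (system rows,
truth columns, order NFD/MFD/AFD), reported unrounded and rounded
half-up to whole percent (87.5 → 88, matching the published rounding).
Cohen's kappa uses the standard `(p_o − p_e)/(1 − p_e)`; note that kappa
recomputed from the published confusion matrices (0.728 / 0.833 / 0.712)
does not match the published coefficients (0.741 / 0.804 / 0.777) —
possibly computed before exclusions or on a different tabulation — so
the package reports its oracle-checked computation and asserts nothing
about the printed values. Distance summaries use per-scan
`|dx|, |dy|, sqrt(dx²+dy²)`, sample SD (n−1) and the normal
approximation `mean ± 1.96·SD/√n` for the 95% CI (the published CIs look
symmetric but name no method; documented so deviations are explainable).
AUROC is the rank-based Mann–Whitney statistic with midrank ties.
`reproduce_paper_summaries` recomputes every published summary that
follows arithmetically from the bundled fixture tables (per-cohort
accuracy, the 195.5 µm unweighted and 162.3 µm case-weighted mean
absolute errors, the 143/240 Spectralis share, the 230-scan validation
size) and reports pass/fail at printed precision.

## Known limitations

* Vendor-proprietary file formats are not read; volumes arrive as
  multi-page TIFF or NIfTI with a JSON geometry sidecar.
* The two-surface search is per-B-scan; cross-B-scan smoothness is only
  implicit (via the denoiser and the centre-of-mass aggregation), unlike
  a full 3D multi-surface graph search.
* IRF is not distinguished from subretinal fluid; the darkest
  sub-ILM region inside the mask is taken as the detection target.
* Classification tunables (prominence 20 µm, smoothing window 5,
  zero-thickness tolerance of one axial voxel) were chosen on phantom
  geometry and are exposed in configuration for recalibration on real
  data.
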