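# Methods

This note documents the models, conventions and numerical choices behind
`msbmap`, and what the synthetic validation does and does not establish.

## Canonical frame and measurement definitions

All geometry lives in a right-handed mm frame: *x* mediolateral, *y*
anterior–posterior (+*y* anterior), *z* craniocaudal (+*z* superior), with
the jugular notch at the origin of the frontal (*x*, *z*) plane.

Unicortical thickness is the *y*-distance from the anterior margin of the
anterior cortex to the anterior margin of the posterior cortex; the
posterior cortex itself is excluded because bicortical drilling is not an
option at this site.  STT is the *y*-distance from the anterior skin
surface to the anterior cortex front.  Both are measured along lines
parallel to *y* — perpendicular to the frontal mapping grid — rather than
along local surface normals: a 1 mm frontal lattice shared by all subjects
presupposes one common probing direction.  A local-normal variant would
differ by a factor cos(slope) (< 4% below 15°); the flag-free projection
definition is used throughout.  Slope is the angle in [0°, 90°] between the
local outward anterior-surface normal and +*y*.

## Surface interrogation

Per-subject maps live on half-open 1 × 1 mm cells anchored on the integer
lattice, value at the cell centre, absent cells encoded explicitly (zero
thickness is a meaningful value).  Because probe lines are parallel to an
axis, ray casting reduces to point-in-triangle tests on the frontal
projection plus barycentric interpolation of vertex *y*; the first
intersection coming from anterior is the largest-*y* hit, and triangles
whose frontal projection is degenerate (grazing, |n·ŷ| ≈ 0) are discarded.
Triangles are bucketed on a 4 mm grid so each cell tests only nearby
candidates.  Cohort aggregation identifies cells across subjects purely by
integer offsets — no interpolation — matching the notch-based alignment.
Slope thresholds are applied strictly (< 15°), configurable to ≤.

An independent voxel-marching probe (`msbmap.probe`) reads thickness
straight off the labeled volume — first cortical voxel from anterior, then
the first cortical voxel after a cancellous run — and shares no code with
the mesh path; the two agree within 2 voxel spacings on phantoms.

## Orientation and alignment

1. **PCA orientation.**  The bone point cloud's smallest-spread principal
   direction becomes the plate normal *y*.  The two in-plane axes are
   assigned, and the superior direction fixed, by a concavity score: the
   configuration in which the boundary's midline indentation (the notch)
   sits at the top scores highest.  The anterior sign comes from the skin
   surface lying at greater *y* than the bone.  Near-isotropic clouds
   (in-plane/normal spread ratio < 1.05) get a degeneracy warning and an
   identity rotation.
2. **Frontal refinement.**  Vertices are trimmed bilaterally at the 5th and
   95th mediolateral percentiles (dropping costochondral-junction
   outliers); if the remaining frontal spread is clearly anisotropic
   (ratio ≥ 1.5) the leading principal direction is snapped to the nearest
   axis.  For near-square footprints second moments carry almost no
   in-plane signal — the same degeneracy that makes a plain frontal-plane
   PCA unusable — so the refinement instead maximises mirror symmetry of
   the 1 mm frontal occupancy about the mid-sagittal line (coarse 0.5°
   scan over ±20°, refined to 0.1°).  The bilateral symmetry of the bone is
   the one in-plane cue that survives the moment degeneracy.
3. **Notch detection.**  The frontal occupancy grid (morphologically closed
   and hole-filled, since mesh vertices can be sparser than the grid) gives
   boundary cells as occupied cells with an empty 4-neighbour.  On each
   side of the midline the boundary point maximal in *y* (literal
   criterion; most-superior *z* available as a config switch) is selected,
   ties toward smaller |x|, and the midpoint of the pair is the notch,
   which is then translated to the origin.  A manually supplied notch
   bypasses detection and is flagged in the output.

## The phantom generator

A phantom is an analytic plate: a superior-wide trapezoidal footprint
(rounded corners, radius 5 mm) with a circular-segment notch cut at the
superior midline; a flat-mid-plane pair of cortical faces; a skin sheet
offset anteriorly by the subject's STT.  The anterior face carries

* two paramedian apical Gaussian protuberances (default amplitude 2 mm,
  σ = 9 mm, centres ±12 mm, 10 mm below the superior edge) — the thickest
  regions of the bone;
* a lateral quadratic falloff and a craniocaudal thickness gradient that
  together cap the anterior-face inclination at `face_curvature_deg`
  (default 10°).  The gradient (0.4·tan θc per mm) is split equally between
  the two cortical faces so the plate mid-plane stays flat — the anatomical
  reading of a plate that thickens superiorly without bending, and the
  property that keeps moment-based orientation unbiased.

Because the faces are explicit functions of (*x*, *z*), the thickness,
slope and STT fields, the notch, and all level scalars are known in closed
form; they are evaluated analytically, never from the emitted meshes.  The
frame is anchored at the point the notch detector ideally finds: the
notch-arc point of maximal anterior *y* (midline by symmetry).  With the
default face the arc beats the notch shoulders and the lateral/inferior
borders by several tenths of a millimetre of anterior prominence, which is
what makes the literal greatest-*y* criterion land on the notch.

Volumes are rasterised at 0.7 mm isotropic (sub-grid relative to the 1 mm
maps) by evaluating the analytic label function at voxel centres — under a
rigid pose, at the pulled-back canonical coordinates, so labels are exact
at any pose.  Labels: background, soft tissue (bone face to skin), cortical
(anterior shell, posterior shell, and a lateral rim within one cortex
thickness of the footprint boundary, via a 0.5 mm Euclidean distance
transform), cancellous elsewhere between the cortices.  HU are independent
truncated normal draws per tissue (cortical 325 ± 73 HU on [100, 1200],
cancellous 60 ± 35 HU on [−200, 500], soft tissue 40 ± 25 HU on
[−300, 300]); simple, controllable, and sufficient for median-HU tests —
no beam hardening, partial volume, kernel or contrast effects.

### Population model

Cohorts draw covariates per subject: sex balanced; body height normal
(172.5 ± 8.1 cm); BMI lognormal with median 22.3 and log-SD 0.22 — the
source data give only a median and a right-skewed range, so the lognormal
is the generator's choice.  Morphometric scalars are exactly linear in the
covariates with the configured effect sizes (sex on thickness at both
levels, on inferior width, on cancellous HU; body height on superior-level
thickness and width; BMI on STT) plus independent Gaussian residuals whose
SDs are set so the marginal SDs match the packaged cohort table.  The
linear "true scalars" are never clipped — they are the regression ground
truth — while the geometric realisation clips separately where physics
requires (e.g. STT ≥ 1 mm, protuberance amplitude ≥ 1 mm so the notch
remains detectable).  The mapping from scalars to spec parameters uses two
constants calibrated once against the default geometry's realised fields
(base thickness ≈ t_IL + 2.28 mm; each mm of protuberance amplitude adds
≈ 0.87 mm to t_SL − t_IL beyond the gradient's 3.22 mm).  Subject *k* of a
cohort uses the deterministic sub-seed `(seed·1000003 + 7919·k + 1) mod
2^31−1`; identical inputs reproduce identical cohorts bit for bit.

## Morphometry and statistics

Level profiles take, per 1 mm craniocaudal row with at least 10 present
cells (excluding notch-fragmented rows), the row **median** thickness
(robust to edge cells; the source measured single slices by hand and gives
no rule) and the width as spacing × present-cell count.  The thickest (SL)
and thinnest (IL) levels are the profile argmax/argmin, ties toward
superior.  Shape is a heuristic taper ratio r = mean width of the inferior
third / superior third: r < 0.70 triangular, 0.90 ≤ r ≤ 1.10 quadrangular,
otherwise trapezoid; thresholds configurable, validated only on synthetic
footprints, never against the visual labels in the packaged table.

Summary statistics use the n−1 SD; confidence intervals are 1000-draw
percentile bootstraps (2.5/97.5), seeded.  Regressions are ordinary least
squares with intercept and normal-theory 95% intervals (statsmodels).
Mode/mean imputation for categorical/quantitative missing values is
available for completeness; the packaged tables have no missing cells.

Rounding for printed-table comparisons is half-up at printed precision
(one decimal for mm, integers for HU).  Two source inconsistencies are
deliberately reported but not asserted: the STT median (running text 14.4,
table column 15.0) and the trapezoid/triangular split (printed rows 26/4,
text 27/3); the quadrangular count (19) is consistent and is checked.

## Density and reliability

The Norton & Gamble class is driven by the cancellous median (the
footnoted "additional type 4" rows are exactly those with negative
cancellous medians); the overlapping printed interval endpoints are
resolved as [500, 850] → 2–3 and [0, 500) → 4, preserving < 0 HU as the
sole failure-zone criterion.  Lekholm & Zarb is visual and is carried as
an annotation only — a computed proxy would have no anchor.  The modified
Hausdorff distance is the Dubuisson–Jain averaged-directed form, the only
standard "modified HD with averaging", computed on 6-connectivity boundary
voxel centres when given masks; Dice of two empty masks is defined as 1.0
with a warning.

## Validation scope and problem sizes

The test and acceptance workloads use 20 phantoms for pose recovery
(rotations up to ±30°/axis, translations ±20 mm), 5 phantoms with 0.7 mm
volumes for map agreement, and 20 cohorts of n = 200 for regression
recovery — sizes at which each check is decisive while the whole suite
runs in seconds.  Passing them shows the chain recovers what the generator
put in: plate-like anatomy with a detectable notch, exact linear covariate
structure, stationary Gaussian HU.  It does not establish performance on
real CT data, whose segmentations carry costochondral junction remnants,
anatomical rotation, scanner-dependent HU shifts and observer variability;
on real data the notch detector in particular is expected to need the
manual override occasionally, which is why it exists and is flagged.  The
residual ≈ 1° orientation bias on default phantoms is the intrinsic cost
of moment-based orientation on a plate with sculpted anterior features,
not an implementation artefact.
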