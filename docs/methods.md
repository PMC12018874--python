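# Methods

`rectvar` quantifies interfraction (day-to-day) positional and shape
variation of a delineated rectal primary gross tumor volume (GTVp) across
repeat MRI scans, the way this is done for planning-target-volume (PTV)
margin work: one baseline delineation, five repeat delineations rigidly
co-registered to the baseline frame on bony anatomy, and two complementary
quantifications — center-of-mass (COM) shifts and per-point surface
displacements — decomposed into systematic (Σ), random (σ) and group-mean
(GM) errors over the cohort.

All coordinates are patient LPS in mm: +x patient left, +y posterior,
+z cranial. Directions are reported as RL (x), AP (y), CC (z).

## Input model

A patient is a set of structure stacks: per scan, planar closed polygons
("contour slices") on a constant axial grid (1.5 mm by default, matching
isotropic 3D T2 acquisition), plus a rigid transform into the baseline
frame, the axial position of the anal verge, and a polyline rectal
centerline. Image registration itself is out of scope: the pipeline
consumes precomputed transforms (rotations bounded at 10°, far above the
~3° a bone match produces) and applies them to point clouds, never by
re-slicing contours — re-slicing would introduce resampling artifacts that
would then need void-removal post-processing.

## Surface sampling

The surface path operates on point clouds, not meshes, because the
surface metric below is defined point-to-point. Each contour ring is
resampled at uniform arc length; the number of points per ring is
proportional to the lateral band area the ring represents — perimeter
times a local slant height estimated from the effective radii
(perimeter/2π) of neighboring slices — so the total count scales as
(surface area)/spacing². Single-contour structures use slant = spacing.
Top and bottom slices additionally receive an interior grid ("caps") so
cranio-caudal motion at the tumor ends is represented. Default spacing is
1.0 mm, which puts realistic study-sized tumors at 7 000–28 000 surface
points.

## COM path

Per slice, polygon area and centroid come from the shoelace formulas; the
volume centroid weights each slice centroid by area × slab. COM
displacement is test-COM (transformed to the baseline frame) minus
baseline-COM, signed +left/+posterior/+cranial.

## Surface path: bidirectional local distance (BLD)

For each baseline surface point b against one test surface:

1. the nearest test point to b (forward match);
2. every test point whose nearest baseline point is b (reverse matches);
3. among these candidates, the farthest one is the mapped point and its
   distance is BLD(b).

The candidate construction makes BLD(b) ≥ the forward nearest distance,
and the maximum of BLD over the baseline cloud equals the symmetric
Hausdorff distance — both asserted in tests, the latter against an
independent Hausdorff implementation. Nearest-neighbor queries use a k-d
tree; near-ties (second neighbor within relative 1e-9) are re-resolved
with exact numpy distances and the smallest-index rule, so the
accelerated path is bit-identical to the exhaustive O(N·M) oracle
(`bld_brute_force`), which exists solely for testing.

Displacement vectors (mapped − baseline) are decomposed into RL/AP/CC and
signed. In-plane, one common sign per point: + if the mapped point lies
outside the baseline structure (motion out of the tumor), − if inside;
applied to |dx| and |dy|. The in/out factor is shared between x and y
rather than signed per component, which is the reading most consistent
with signing "the in-plane components" by a single in/out event. CC is
signed outward/inward relative to the axial plane through the baseline
COM: + when the z-displacement points away from that plane. Boundary
containment classifies as outside; a sign flip at distance ≈ 0 is
numerically irrelevant.

## Statistics

Fixed conventions, since several are underdetermined in common usage:

* percentile: linear interpolation between order statistics
  (h = 1 + (n−1)q/100); median = p50, IQR = p75 − p25. With ~10⁴ surface
  points the convention is immaterial; over 12–16 patients it is not,
  hence fixed.
* SD: sample (n−1) denominator at both patient and population level.
* Van Herk decomposition over patients p with per-patient per-direction
  mean m_p and SD s_p:
  GM = mean_p(m_p), Σ = SD_p(m_p), σ = sqrt(mean_p(s_p²)).
  Note Σ estimated this way includes a σ²/M inflation (M = scans per
  patient); no correction is applied, matching standard practice.
* Surface patient summary ("surface_p95"): per point, mean and SD of the
  signed displacement across the patient's test scans first, then the 95th
  percentile over points of the means and of the SDs. The alternative
  order (per-scan p95 first, then moments across scans) is available as
  `mode="scan-p95-moments"` for sensitivity analysis; the default order is
  the one that "selects regions with the largest positive mean and SD per
  patient".

## Reference-rectum mapping

To resolve variation by wall direction and tumor height, per-patient
statistics are mapped to a common reference rectum: a straight tube along
+z, radius 15 mm, slices every 1.5 mm from 0 to 130 mm central-axis (CAX)
distance from the anal verge, 120 surface points per slice at 3° spacing,
0° = anterior, counter-clockwise toward patient left. Radius and spacing
are configurable — the appropriate reference geometry is a modeling
choice, not an anatomical constant.

Each patient baseline point gets a CAX coordinate (arc length along the
patient centerline from the anal verge to the nearest centerline vertex)
and is re-expressed about the reference axis by translating its
centerline foot onto the axis at the same CAX. The reverse-nearest step
of the BLD mapping then assigns every patient point to exactly one
reference point (mass conservation is asserted). Per reference point and
patient, mapped points' per-point means/SDs are averaged before
inter-patient statistics, so large tumors cannot dominate the variance.
Inter-patient Σ/σ/GM maps are computed where at least `min_patients`
(default 5) patients contribute; understaffed points are masked and never
enter any summary.

Segments: four 180° directional halves (anterior/posterior use the AP
maps, left/right the RL maps; each slice point belongs to exactly two
halves) × three height bands (low 28–51, mid 52–100, high 102–130 mm
CAX). Per segment the median, IQR and p95 of the Σ, σ and GM maps over
valid points are reported.

Cranial/caudal rows use only the top and bottom slices of each baseline
tumor, in the CC direction. Those slices sit at different heights per
patient and cannot be aligned pointwise, so the rows are computed as a
quantile profile: at each q ∈ {25, 50, 75, 95}, every patient contributes
the q-th percentile over its top (bottom) slice points of per-point CC
means and SDs; inter-patient Σ/σ/GM are then formed at each q. The median
row is the q=50 profile, the p95 row the q=95 profile, and the IQR row is
the q=75 minus the q=25 profile. This is one defensible reading of an
underdetermined construction and is isolated in `cc_extremes`.

## Synthetic cohorts

Real repeat delineations of rectal tumors contain sensitive personal data
and are not distributable, so validation runs on generated cohorts whose
ground truth is known exactly.

Geometry: a wall-hugging tumor with crescent axial cross section on a
tubular rectum (radius 15 mm, straight centerline, anal verge at z = 0).
Per patient the distal tumor border follows a deterministic ladder over
the cohort (low tumors 8–50 mm from the verge, 13 of 16 in the
study-like preset; mid tumors above 55 mm, location labeled by the distal
border as in clinical practice), and one size draw couples height
(36–66 mm), angular extent (280–320°), wall thickness, extramural bulge
and a lobulated wall ripple. Height grows with ladder position so no
reference slice is shared by every patient; with 16 patients the
per-slice occupancy spans 1–12. The ripple emulates the wrinkled surface
of advanced tumors and brings baseline clouds into the 7 000–28 000-point
range at 1 mm spacing.

Motion: per direction, rigid shifts gm + s_p + r_pk with s_p ~ N(0, Σ)
drawn once per patient and r_pk ~ N(0, σ) per scan — the implicit model
behind the Σ/σ/GM decomposition. Offsets are quantized to 1 µm (far below
delineation precision) so canonical 6-decimal serialization is exact.
Each patient draws from an independent seeded stream, so growing a cohort
never reshuffles earlier patients. A `moment_match` mode standardizes the
drawn offsets to the requested moments exactly (systematic draws to mean
gm and SD Σ; per-patient random draws centered and scaled to SD σ); it
exists for parameter-recovery validation, where it isolates pipeline
error from Monte-Carlo sampling error — with it, the COM path must
recover the generating parameters to numerical precision, and does.

Deformation: a volume-balanced "breathing" mode, radial displacement
d(θ, z) = A sin(mθ + φ) g(z) with m ≥ 2 lobes and a Gaussian axial
profile (default σ_z = 30 mm), phase and axial center persistent per
patient, amplitude jittered per scan. Because in- and outward crests
balance, tumor volume and COM stay essentially still while surface points
move by up to the full amplitude — the regime in which COM-based analysis
underestimates local deformation, which the pipeline must (and does)
expose via the surface path.

What the generator does not emulate: delineation uncertainty, tumor
regression over the treatment course, rotational misregistration effects
beyond the rigid-transform plumbing, curved rectal centerlines, and
MRI intensities of any kind. Passing tests therefore demonstrate
correctness of the computational pipeline under the stated motion model,
not clinical performance on real delineations.

## Numerical notes and limitations

* Tie-breaking everywhere is "smallest point index", making all mappings
  deterministic and oracle-comparable.
* Analysis stages are fully deterministic; randomness exists only in the
  simulator, always behind an explicit seed.
* BLD measures distance to the nearest/assigned point, which captures the
  surface-normal component of motion. On heavily wrinkled surfaces
  (steep local normals) recovered displacement can be substantially
  smaller than the imposed radial motion — in our experiments a wall with
  ripple slope ≈ 2 attenuated recovered amplitudes to roughly 0.4×. The
  deformation-sensitivity demonstrations therefore use smooth-walled
  tumors; conclusions about wrinkled anatomies need that caveat.
* Problem sizes used in validation: BLD oracle comparisons at N, M ≤ 300;
  parameter recovery on 200 patients × 5 scans (COM path only); the
  end-to-end study-shaped run on 16 patients at 1 mm sampling
  (8 000–20 000 points per cloud); deformation contrast on 8 patients at
  1.5 mm sampling.
* Single-slice structures take a 1.5 mm nominal slab for containment and
  sampling; zero-area structures are rejected.
* PTV-margin recipes (e.g. 2.5Σ + 0.7σ) and confidence intervals on Σ/σ
  are intentionally out of scope.
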