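# Methods

## The phantom model

The synthetic substrate emulates high-resolution temporal-bone CT: a block
of dense bone (1800 HU) containing a dark fluid-filled inner-ear lumen
(30 HU). The lumen is the union of

* an **ellipsoidal vestibule** (default semi-axes 2.5 × 1.5 × 1.5 mm, long
  axis along the duct course, placed tangent to the vestibule-exit plane so
  that it never protrudes onto the duct side), and
* the **vestibular aqueduct**: a tube of circular cross-section centered on
  a planar circular-arc course (default length L = 10 mm, bend radius
  20 mm), cut flat by radial planes at both ends. The whole course plane
  is rotated 15° out of the axial plane, so the duct descends steadily
  (z-span ≈ L·sin 15° ≈ 2.6 mm) and every local tangent is about 15°
  oblique to the slices — the regime in which axial caliper measurement is
  clinically performed.

The tube radius r(s) over normalized course position s ∈ [0, 1] is a
monotone (PCHIP) interpolant through three control radii — vestibule exit,
midpoint, operculum — which realizes the three shape archetypes observed
in inner-ear malformation: near-uniform ducts, central dilatations
(r_mid dominant) and operculum funnels (r_oper dominant). PCHIP is used
because it cannot overshoot: r(s) stays within the control radii, so
positivity and the bend-radius constraint are inherited from the controls.

**Analytic volume.** Because every cross-section is a disk centered on
the course and the end cuts are radial, the enclosed volume is exactly
∫₀ᴸ π r(s/L)² ds: decomposing the bent tube in polar shells, the
first moment of a disk about its own center vanishes, so curvature
contributes nothing (a Pappus argument). The quadrature of this integral
(adaptive, relative tolerance 10⁻⁹) is therefore an exact oracle for the
digitized volume, not an approximation — the often-quoted curvature
correction of order (r/R)² cancels identically for this construction.

**Digitization.** Each voxel's pre-noise HU is
`bone + (fluid − bone) · coverage`, with coverage the fraction of the
voxel inside the lumen. Voxels near the lumen surface (identified by a
conservative clearance bound of half a voxel diagonal) are resolved by
3³ supersampling; interior/exterior voxels are assigned exactly. Gaussian
blur (default σ 0.3 mm for single phantoms) and seeded Gaussian noise
(default 40 HU) follow. The truth label map marks voxels with VA-tube
coverage > 0.5 — the duct between the vestibule-exit plane and the
operculum cap, excluding the vestibule.

## Segmentation

The semi-automatic protocol is: threshold to the −1024…700 HU band
(inclusive at both ends), label 26-connected components (thin,
anisotropically sampled ducts fragment under 6-connectivity), keep the
component containing the operator's seed, and clip at two oriented planes
— the VA exit from the vestibule and the operculum end plane. The band's
upper limit of 700 HU corresponds, at the default contrast, to a coverage
iso-level of (1800 − 700)/(1800 − 30) ≈ 0.62 rather than 0.5, so the
thresholded surface sits ≈ 0.12 voxel inside the true lumen boundary.
The resulting volume bias is about −3% for ducts a few voxels across at
0.2 mm isotropic sampling, and grows for ducts approaching the voxel
size — the partial-volume regime that makes narrow-duct volumetry hard in
practice. A seeded selection may optionally snap to the nearest foreground
voxel within a stated tolerance (used by the pipeline to model an
operator re-clicking a near-miss on a thin duct; strict by default).

## Measurements

* **Volumes.** Voxel volume is foreground count × voxel volume. Mesh
  volume is the divergence-theorem sum of signed tetrahedra over a
  watertight marching-cubes surface of the 0.5 level of the binary mask
  (zero-padded so the surface always closes; orientation fixed to
  outward). The mesh volume is the headline VA volume; the voxel volume
  is reported alongside.
* **Centerline.** 3D topological thinning of the mask; shortest path on
  the 26-neighbor skeleton graph (edges weighted by physical length)
  between the skeleton voxels nearest the vestibule-exit and operculum
  landmarks; the landmark points themselves are prepended/appended and the
  skeleton part is smoothed by a 3-point moving average, then the polyline
  is arc-length parameterized.
* **Caliper widths.** A diameter is measured on the axial slice through
  the station point, along the in-slice line perpendicular to the in-slice
  projection of the local course tangent (caliper practice on axial
  images; for an oblique cylinder this direction reads exactly 2r, the
  ellipse minor axis). The lumen-occupancy field — attenuation mapped
  linearly between robust bone and fluid anchors, gated to the dilated
  mask — is sampled by trilinear interpolation at steps of a quarter of
  the in-plane spacing, and the width is the distance between the
  outermost 0.5 crossings (a first-crossing variant is available behind a
  flag). Sampling the continuous field rather than the binarized mask
  keeps the caliper sub-voxel accurate; blur does not bias it because a
  Gaussian preserves the half-level of a step edge. A caliper whose line
  never reaches the lumen near the station reads 0 and the record is
  flagged.
* **Stations.** The midpoint station is half the centerline arc length.
  The operculum station is one voxel inside the duct end: on the exact
  end cap the digitized field sits on the 0.5 level and the width
  collapses to a sliver, so the last station with a full cross-section is
  used; the operculum tangent is taken from the last 1 mm of the course.

Records are flagged `under_resolved` when a measured width falls below
twice the largest voxel dimension, and `volume_mismatch` when voxel and
mesh volume disagree by more than 15%.

## Classification

Cincinnati (operculum > 1.9 mm and/or midpoint > 0.9 mm, inclusive-or),
Valvassori (midpoint > 1.5 mm) and the volumetric rule (> 15.4 mm³), all
with strict inequalities so boundary values classify as normal. Whenever
Valvassori fires, Cincinnati fires too (1.5 > 0.9). Thresholds are
config-overridable.

## Cohort calibration

Per group (control, CH, IPI, IPII, EVAS; default sizes 42/18/12/11/15),
the operculum and midpoint radii are drawn from log-normal distributions
whose **truncated** median equals the published group median (the
underlying log-median is solved for by root finding, since truncation
otherwise shifts the median); the log-sd is derived from the published
interquartile ratio, capped at 0.5 so the group median is a stable summary
at simulation sample sizes — the heavy CH/IPI quartile spread is therefore
under-represented, a deliberate trade of dispersion fidelity for median
fidelity. Draws are truncated by resampling to the published observed
range, with a 0.15 mm radius floor so every duct is resolvable at the
default 0.2 mm voxels; the control midpoint is truncated at 0.45 mm
radius, matching the reported control population (all midpoints
≤ 0.9 mm). The exit radius (not published) is log-normal at 0.6× the
group's midpoint median; course length is log-normal around 10 mm.
EVAS draws are rejection-sampled to an analytic volume above 18 mm³,
emulating the reported complete separation of the EVAS group from
controls on the volume axis. Everything is seeded through
`numpy.random.SeedSequence`, one stream per ear, so cohorts are
reproducible ear-by-ear.

Default cohort imaging is the noise-free study condition (0.2 mm
isotropic, no blur, no noise); blur, noise and anisotropic spacing are
exposed for degradation experiments. With the default 0.3 mm blur, ducts
below ≈ 0.6 mm diameter rise above the threshold band and are lost —
realistic partial-volume behavior that the pipeline surfaces as a
segmentation failure rather than a silent zero.

## Rater model

Each of two raters receives independently perturbed landmarks: seed,
vestibule-exit and operculum points displaced uniformly within a 0.3 mm
sphere; the caliper angle jittered uniformly within ±10°; and the
measurement slice jittered by ±1 slice. A slice offset is realized as
moving the station along the centerline to where the course crosses the
chosen slice (a rater re-centers the caliper on the duct in that slice);
for a near-axial course segment the adjacent slice shows the same
cross-section and the station does not move. Volumes react only through
the perturbed clip planes (a fraction of a cubic millimeter), while
diameters react through station, angle and centerline changes — which is
why the volumetric ICC(2,1) systematically exceeds the caliper ICCs, the
operculum (steepest radius gradient) being the least reliable. This
reproduces the qualitative reliability ordering reported for the clinical
measurements.

## Statistics

All tests are nonparametric, matching the study protocol. Kruskal–Wallis
uses the tie-corrected H with a χ² upper tail; for pooled n ≤ 8 an
exhaustive permutation p-value is attached. Dunn's z uses pooled mean
ranks with the tie term, Bonferroni-adjusted by default (Holm and
unadjusted available); exact permutation p-values are attached at pooled
n ≤ 8. Spearman switches to the exact permutation null for n ≤ 9.
The Hodges–Lehmann shift estimate is the median of all pairwise
differences (b − a), with the Moses order-statistic CI bracketed by the
exact Mann–Whitney null CDF (computed by the box-partition recurrence;
normal approximation beyond 20 000 pairwise differences). ICC is fixed to
ICC(2,1) — two-way random effects, absolute agreement, single measures —
the conservative standard for two interchangeable raters rating all
subjects. ROC candidate thresholds are the unique observed scores plus
−∞ under a strict-greater positive rule (matching the "> cutoff" phrasing
of the volumetric criterion); Youden ties resolve toward maximum
sensitivity, then the smallest threshold, so on separable data the cutoff
lands on the largest negative score and `score > cutoff` separates the
classes exactly. Sensitivity/specificity CIs are Clopper–Pearson.

## Problem sizes

The default study measures 98 ears at 0.2 mm isotropic sampling (about
12 s); the reliability experiment uses 20 replicate cohorts of 12 ears
(about 40 s); calibration medians are checked at 200 ears per group.
These sizes make the stochastic checks stable while keeping a full
reproduction run around one minute.

## Known limitations

* Axis-aligned geometry only; rotated/oblique CT volumes are rejected
  rather than resampled, and no DICOM ingestion is provided.
* The bone/fluid HU levels, blur and noise are plausible HRCT settings,
  not fitted to clinical scanners; the absolute volumetric cutoff found on
  synthetic cohorts (≈ 5–7 mm³) reflects the synthetic control/EVAS
  geometry, not the clinical 15.4 mm³ operating point.
* Group quartile spread is compressed for CH/IPI (log-sd cap), and the
  cochlea and semicircular canals are not modeled; passing tests show
  correct recovery of tube-like ducts from threshold-segmentable images,
  not performance on real temporal bones.
* Sub-voxel ducts (radius ≲ the voxel size) are systematically
  under-segmented by the fixed HU band; volume-recovery guarantees apply
  to ducts whose minimal radius is at least twice the largest voxel
  dimension.
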