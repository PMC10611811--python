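# Methods

This note documents the model behind `ctpa-cade`: what each stage assumes,
the parameters that matter, what the synthetic phantom does and does not
emulate, and the numerical choices that were genuinely open.

## Coordinate and display conventions

All volumes are stored as `(slice, row, col)` arrays of Hounsfield units
with slice 0 the most cranial slice. In the axial display convention used
throughout, *anterior* is decreasing row index and *patient-left* is
increasing column index. Readers normalize DICOM series (sorted by patient
z, rescale slope/intercept applied per slice), NIfTI (via the RAS canonical
form) and NRRD (axial LPS only) into this frame; non-axial acquisitions
(direction cosines > 5° off-axis) are rejected rather than resampled.
Distances and thresholds are always expressed in millimetres and converted
to pixels per volume, so decisions are invariant to in-plane spacing.

The working slice thickness is 2.0 mm. Thinner input is reformatted by
overlap-weighted window averaging along the slice axis (mean-preserving;
plain block averaging at integer thickness ratios). Whether a scanner
console averages or interpolates its 2 mm reformat is generally unknowable
from the exported data; window averaging is the simplest choice consistent
with partial-volume physics. Thicker input is refused — upsampling would
fabricate resolution.

## Orientation normalization

Patient rotation can differ between the cranial and caudal thorax
(scoliosis, positioning). Each end of the exam gets an in-plane angle
estimate: the body mask (HU > −500, largest component, interior holes
filled so the lungs do not flip the principal axes, a table-removal
heuristic for wide bottom-touching components) is reduced to its second
moments, and the bilateral symmetry axis is the principal axis
perpendicular to the body's elongation. The correction angle is linearly
interpolated between the cranial and caudal estimates and applied as a
per-slice bilinear rotation with −1000 HU fill.

Two guards matter in practice:

* estimates beyond ±25° are treated as unreliable and the volume passes
  through unrotated (flagged), because a thorax estimate that large is more
  likely a segmentation failure than true positioning;
* estimates below 1° are treated as identity. Interpolating a sub-degree
  rotation buys no geometric accuracy but low-pass filters the noise
  texture, which would corrupt the downstream noise-SD measurement — a
  deliberate trade of negligible geometric error for measurement fidelity.

## Airway stage

Air is HU < −800: low enough to exclude lung parenchyma (≈ −850 HU means
roughly half of parenchyma pixels, but parenchyma components fail the size
filters anyway; the lumen of trachea and bronchi sits near −1000).
Exterior air is removed by flood-filling from the in-plane borders of the
stack only — deliberately not from the cranial/caudal faces, because a
tracheal lumen open at the first slice must survive.

Trachea candidates are 26-connected 3D components within two stacked
volumes of interest (slices [0, 15%) and [15%, 35%) of the stack, in-plane
extent the body bounding box), filtered to median per-slice equivalent
diameter 8–30 mm and volume 2–60 cm³ — adult tracheal anatomy with margin;
all four bounds are config keys. Candidates are joined across the VOI
boundary when their facing centroids are within 10 mm, and the longest
surviving candidate wins (ties: larger volume, then closer to the vertical
midline).

Tracking proceeds slice by slice caudally; the bifurcation is the first
slice where ≥ 2 distinct air components continue the lumen. The carina is
the first slice caudal of that where the left–right bronchus gap strictly
exceeds 7.5 mm. The gap is the minimum edge-to-edge distance: boundary
pixel centers' distance minus one pixel extent (each boundary pixel reaches
half a pixel beyond its center), which makes an exactly-7.5 mm rasterized
gap test negative under the strict inequality, as required. A
centroid-distance variant is available behind `airway.gap_metric`.

## Vessel primitives

*Region growing* nominally adds 8-connected pixels while
|HU − running region mean| ≤ 100 HU. A literal running mean depends on
visit order; here the criterion is evaluated as a deterministic fixed
point — the connected component of the thresholded homogeneity image
containing the seed, mean re-estimated per iteration until stable — which
is what makes seed-position invariance and byte-identical reruns provable.
Growth cannot cross edge pixels (Canny: Gaussian-smoothed gradient
magnitude, non-maximum suppression, hysteresis at the 70th/90th
gradient-magnitude quantiles inside the body mask); enclosed holes from
noise or interior edges are filled. Regions exceeding 4000 mm² are flagged
overgrown and treated as failures (the largest legitimate single-vessel
cross-section, a 35 mm trunk's elongated outflow, is ≈ 2800 mm²; a merged
two-vessel region exceeds the cap).

*Half-maximum refinement* then re-thresholds the neighbourhood at the
midpoint between the region's core mean (2-px-eroded mask) and the local
background (median HU in a ring 4–9 px outside the mask). This places the
boundary at 50% intensity, which is what makes area — and hence diameter —
estimates unbiased across the 200–600 HU contrast range: a fixed-tolerance
criterion alone would over-segment low-contrast and under-segment
high-contrast vessels. The ring is kept clear of the grown boundary so an
edge-blocked, slightly under-grown mask cannot contaminate the background
estimate.

*Circularity* is 4π·area/perimeter² with both quantities taken from the
marching-squares outer contour polygon, lightly smoothed along the contour
(3-vertex cyclic moving average). Pixel-count perimeters systematically
inflate for rasterized discs; the smoothed polygon scores a disc ≈ 0.97 and
a square ≈ π/4, so the circularity gates (below) act on shape, not on
rasterization.

*Ray casting* walks each direction at half-pixel steps with bilinear
sampling; a hit requires the first in-range pixel within the ray length
(50 mm) and a contiguous in-range run ≥ 10 mm. The length bounds where the
structure may *begin*; a run that starts near the end of the ray is allowed
to complete, since run length is a property of the vessel, not of the
search radius.

*Hough diameter* uses a circular Hough transform over the mm-converted
radius range on a Canny edge map, with parabolic sub-pixel interpolation of
the accumulator across the radius axis. On noise-free rasterized discs
(radii 5–25 mm, spacings 0.6–0.9 mm) the diameter error stays within one
in-plane pixel — the test suite checks 200 random cases.

## The chain's vessel stages

All geometric defaults are named config keys; none are learned.

| parameter | default | role |
|---|---|---|
| ray fan / step | ±45° / 5° (refine ±10° / 2°) | DAo search posterior to the left main bronchus |
| ray length / min run | 50 mm / 10 mm | how far the DAo may sit; what counts as aorta |
| vessel HU range | 150–1200 HU | admits poorly enhanced exams (< 200 HU), excludes bone/metal |
| DAo propagation | ±30 mm, circularity ≥ 0.7, area 50–150% of carina level | slice-to-slice continuity |
| arch trigger | area > 1.8× carina DAo, or circularity < 0.6 | the two limbs merging into the elongated arch |
| AAo floor | circularity ≥ 0.8 within 30 mm caudal of arch | "first circular object" |
| PT search box | 40×40 mm abutting the AAo's left boundary, ≤ 20 mm caudal of carina | where the trunk lives |
| PV rule | circularity ≥ 0.85 after having been below | elongated outflow → round proximal trunk |
| PT tracking | ≤ 50 mm caudally | bounds the valve search |

Two measurement conventions are intentionally asymmetric: the AAo diameter
is the mean equivalent-circle diameter of its segmented planes between arch
and carina (planes failing the 0.8 circularity floor — arch remnants — are
excluded from the mean, since a diameter of a non-circular section is not
well defined), while the PT diameter is the mean of per-slice Hough-circle
diameters over the tracked planes. The PV comparison direction
(below → above) is config-switchable (`pipeline.pv_transition`), as the
transition could plausibly be read either way; the default reflects the
outflow tract being elongated and the proximal trunk round.

When the anterior part of the arch is tracked caudally, the tracking point
is the centroid of the pixels within 12 mm of the region's most anterior
row (not of the anterior third): for small aortas the anterior third of the
long arch band extends past the AAo footprint and its centroid can land in
tissue between the limbs.

Measurements: noise is the SD of HU in a 1 cm² disc at the DAo mass center,
contrast the mean in a 2 cm² disc at the PT mass center, both on the slice
that best presents the PT (maximum tracked PT area; config-switchable to
the carina slice). A disc that does not fit inside the segmented region is
recentered at the region's inscribed-circle center and otherwise soft-fails.

## The phantom generator

The phantom is the package's validation surface. It renders, on an
elliptical soft-tissue thorax (40 HU, 3 mm high-attenuation rind, air
background) with two lung fields (−850 HU):

* an 18 mm air trachea bifurcating into 12 mm bronchi that diverge
  1.75 mm/slice from an initial ±7 mm offset — so the carina level
  (edge gap > 7.5 mm) is analytically two slices below the bifurcation;
* a contrast-filled aorta modelled as two vertical limbs (AAo anterior and
  slightly patient-right, DAo posterior-left of midline behind the left
  main bronchus) joined cranially by a horizontal connecting tube. The
  tube produces the merged, elongated axial cross-section that the arch
  trigger keys on, while keeping both limbs circular below it, so the
  equivalent-diameter measurement has no oblique-section bias. The truth
  arch level is the most caudal slice intersecting the tube;
* a pulmonary trunk left-lateral to the AAo whose cross-section is an
  elongated stadium (straight length 3 radii; circularity ≈ 0.76) above
  the pulmonary-valve level and a circle below it. The stadium's cap
  radius equals the trunk radius, so the Hough estimate is exact even on
  the elongated planes;
* optional degradations: seeded Gaussian noise, streak bands radiating
  from a dense venous focus, motion blur, per-slice in-plane rotation
  (evaluated analytically on rotated coordinates — no interpolation), an
  esophageal air tube, and deletable structures for soft-failure fixtures.

Geometry is rendered at 2× in-plane supersampling and box-averaged down,
giving partial-volume boundaries and rasterized diameters accurate to
≤ 0.5 voxel. Truth masks are computed before noise; truth values are the
generator's inputs (or analytic consequences), never re-measurements.
Compartment truth masks carry the chain's measurement extents (DAo within
±30 mm of the carina, AAo between arch and carina, PT from the carina to
at most 50 mm caudally), which is what a Dice score against the chain's
output should be conditioned on.

The noise field is white Gaussian noise standardized per pixel by its local
windowed mean and SD (window ≈ the diameter of a 1 cm² ROI) and scaled to
the nominal SD. A raw white field's sample SD inside a single 204-pixel ROI
fluctuates ±5% (1σ), which would make the ±10% noise-recovery check a coin
flip across a 50-phantom cohort even with a perfect measurement; the
standardized field keeps any ROI-sized window's SD within ~3% of nominal
while remaining zero-mean and spatially white at the scales that matter.
Volumes are quantized to integer HU so serialization is lossless.

Default parameter values are population medians of a large clinical CTPA
cohort: AAo 33 mm, PT 27 mm, DAo 25 mm, contrast 385 HU, noise 20 HU at
2.0 mm slices, 0.7 mm pixels, ~146-slice stacks (the phantom uses 100
slices — enough to carry all structures plus margin). Cohort sampling is a
Latin hypercube over AAo 20–40 mm, PT 18–35 mm, contrast 200–600 HU, noise
5–35 HU, with the DAo tied to 0.75× the AAo (clipped 16–30 mm).

**What passing on phantoms does and does not show.** The phantom exercises
the chain's geometric logic (search spaces, tracking, gates), its
measurement accuracy under noise, and its failure accounting. It does not
model real anatomy's variability — curved and tortuous vessels, the heart,
pathology, beam hardening, real streak physics, non-circular vessel
sections — so phantom-world detection rates and Dice scores are upper
bounds, not predictions, for clinical data.

## Evaluation metrics

Dice is 2|A∩B|/(|A|+|B|), 1.0 for two empty masks. Boundary F1 extracts
boundaries as mask voxels with a background 4-neighbour in-plane, pools
boundary voxels over slices, and scores precision/recall as the fraction
within the tolerance (default 2 in-plane voxels, config-exposed, as is the
pooled-vs-per-slice choice) of the other boundary, distances by Euclidean
distance transform with mm sampling. Bland–Altman uses d = x − y, limits of
agreement mean ± 1.96 sample SD (ddof = 1), percentage differences against
the pairwise mean (the standard percent convention); Pearson r is reported
for n ≥ 3 and non-constant input.

## Problem sizes and determinism

The validation sweep uses 50 phantoms of 100×320×320 voxels; the full sweep
(generation + detection + scoring) runs in a few minutes on one CPU, and
`scripts/acceptance.py --seed N` reproduces its JSON exactly for a given
seed. The chain itself contains no randomness; the only seeds in the
package are the phantom generator's.

## Known limitations

* The chain assumes near-axial, contrast-enhanced chest CT at ~0.6–0.9 mm
  pixels; it refuses rather than adapts outside that envelope.
* Heart chambers, ventricle ratio and caval reflux are out of scope.
* The visual quality sub-scores (motion, streak, parenchyma) are inputs to
  `classify_quality`, not computed — only noise and contrast have automatic
  counterparts.
* Wall-clock stage timings are reported for information only; they are
  hardware-dependent and carry no accuracy claim.
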