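# Methods

`caulotype` is a trainable image-analysis pipeline for quantifying the
dimorphic cell types of stalked bacteria (the *Caulobacter crescentus*
swarmer / stalked / predivisional taxonomy) from 2-D phase-contrast
micrographs, together with a synthetic micrograph generator that provides
exhaustive ground truth so every stage can be tested at desk scale. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## The synthetic micrograph generator

**Geometry.** A cell body is a capsule of *total pole-to-pole extent L*:
a disk of radius `width/2` swept along the centerline trimmed by
`width/2` at each end, so the polyline endpoints are the poles and the
stated cell length equals the tip-to-tip extent. Centerlines are circular
arcs (curvature ~ N(0.3, 0.12) µm⁻¹, sign random) giving the crescentoid
habit. A division constriction is a Gaussian-profile width reduction
(waist sd 0.22 µm) of fractional depth `constriction_depth` at
`constriction_position` of the arc length. Stalks are gently wandering
polylines of width 0.15 µm — well below the resolution limit — grown
outward from one pole, rasterized with the same extent-L convention and
rendered at 55% of the body contrast, so they appear as faint thin lines,
as in real phase-contrast images.

**Morphology presets** (truncated normals, all in µm): nutrient-replete
exponential growth — swarmer length 1.9 ± 0.3, stalked 2.6 ± 0.4, stalk
1.2 ± 0.5, mixture ST/SW/PD/debris = 0.50/0.35/0.10/0.05 (stalked plus
predivisional ≈ 70% of counted cells, matching an exponential-phase
population); carbon/nitrogen limitation — 15% shorter, swarmer-enriched
(0.40/0.48/0.07/0.05); phosphate limitation — filamentous bodies
4.5 ± 1.5 with stalks 8 ± 3, and no swarmers among non-debris cells
(phosphate-starved cells complete the swarmer-to-stalked transition but
cannot divide). These magnitudes are fixture conventions chosen to be
biologically plausible, not measured claims.

**Debris** is an object-level class covering what a curator would
exclude: strongly defocused cells (extra blur ≥ 3 x the PSF sigma) and
small lysed fragments. The generator avoids debris-on-cell overlap so
that ground truth stays unambiguous; real fields contain overlapping
cells that this benchmark therefore does not probe.

**Optics and noise.** Default frame 2048 x 2048 px at 0.065 µm/px — a
133.12 x 133.12 µm field of view. Dark bodies on a bright background
(background 30 000 counts, body contrast 12 000 on the 16-bit scale), a
bright halo approximated by a difference of Gaussians (PSF sigma 0.09 µm,
halo sigma 0.40 µm, amplitude 0.55 of contrast) rather than a physical
phase-ring model, a low-order linear illumination gradient (± 2%), and
signal-dependent photon noise (sd = 1.6 sqrt(signal)) plus additive read
noise (sd 120). Per-object defocus is extra Gaussian blur. Truth masks
are the noise-free rasterizations of the nominal geometry; truth lengths
are the analytic polyline arc lengths. Every output is a pure function of
(configuration, seed).

**Placement** is rejection sampling: non-debris bodies keep ≥ 0.25 µm
clearance, stalks keep ≥ 0.05 µm clearance from other bodies, and all
geometry stays 0.4 µm inside the frame. A field too small for the
requested count raises an error naming the achieved count.

## Pixel classification

Features are the trainable-segmentation standard: raw intensity plus
{Gaussian smoothing, gradient magnitude, Laplacian, larger/smaller
Hessian eigenvalue} at sigmas (1, 2, 4, 8) px — 21 channels, reflective
boundaries. Sigmas above 2 px are computed on a block-mean pyramid
(downsampled by the largest power of two keeping the effective sigma
≥ 2 px, bilinearly upsampled); at those scales the responses are smooth
and the approximation error is far below the noise floor, while the
dominant convolution cost drops several-fold.

The classifier is a 100-tree random forest (unlimited depth, seeded,
single-thread). Training subsamples a balanced set of up to 12 000 pixels
per class, pooled over images; half of the background sample is drawn
from the dilated neighbourhood of foreground, because halo pixels are the
hard negatives. The cap of 12 000/class keeps a single-core fit under
half a minute; fixture accuracy was indistinguishable from larger caps.
Per-image sampling is keyed to a content digest and images are pooled in
digest order, so the model is invariant to training-set order; the digest
also goes into the model file for provenance.

Prediction applies a background prescreen: a pixel whose sigma = 1.5 px
smoothed intensity stays within 4 robust standard deviations (MAD) of a
large-scale background estimate — after removing isolated speckles and
then dilating detections by 8 px — is assigned background probability 1;
the forest is evaluated only on the remaining candidate pixels (a few
percent of a default frame). The threshold sits far below the faintest
rendered structure (a stalk's smoothed dip is tens of noise sd), and the
stalk-recall tests exercise the full path, so a prescreen miss would be
visible. Argmax ties break background < cell body < stalk.

## Object analysis

Cell bodies: threshold the body probability at 0.5, fill holes, label
8-connected components, and split touching cells with a marker-based
watershed on the smoothed body probability. Markers are the h-maxima of
the distance transform with prominence h = 0.24 µm (0.3 x the 0.8 µm
marker-separation scale): a division waist is a shallow saddle and never
splits a predivisional cell, while genuinely touching cells separate.
Components below 0.4 µm² or touching the frame border (partial cells
would bias lengths; configurable) are dropped.

Stalks: threshold the stalk probability at 0.5, thin each component to a
one-pixel skeleton, keep the geometrically longest path (which prunes
side spurs), extend its ends along the local tangents to the mask
boundary, and filter on length ≥ 0.3 µm and mean width ≤ 0.35 µm.

Object features: area, perimeter, raw skeleton length, mean/min width,
solidity, eccentricity, mean body probability, a focus score (RMS
Laplacian response inside the object over the image-wide robust scale),
and the count/total length of attached kept stalks (attachment = skeleton
endpoint within 0.25 µm of the cell contour). Stalk features: length,
mean width, straightness, mean stalk probability, endpoint-to-nearest-
cell distance. Objects under 3 px are flagged degenerate, given sentinel
features, and auto-classed debris.

Cell classification is a 200-tree random forest over these features,
trained on segmented objects labelled by majority overlap with the truth
instance masks. A transparent rule-based fallback (debris if focus score
< 3; stalked iff attached stalk length ≥ 0.8 µm) exists for deterministic
tests. Stalk keep/remove uses explicit rules by default (keep iff an
endpoint lies within 0.5 µm of a cell and mean stalk probability ≥ 0.5);
a trainable stalk classifier with the same interface is available when
both labels exist. Debris classification never deletes pixels — exclusion
is downstream bookkeeping.

## Morphometrics

**Cell length** is the arc length of the pole-extended medial axis:
skeletonize the instance mask, reduce to the longest path (weighted pixel
graph, two-sweep Dijkstra diameter), smooth with a moving average pinned
at the endpoints, and march each end along its local tangent in
quarter-pixel steps until leaving the mask. The extended endpoints are
the poles. Width at each vertex is `2 * (EDT - 0.5 px)`, with the mask
padded before the distance transform: the padding stops a tight bounding
box from hiding the background, and the half-pixel term corrects the
distance-to-pixel-centre bias (without it a 7-px waist reads as 8 px).
Masks with no elongation axis (skeleton shorter than the maximal inscribed
radius) raise a degenerate error and the cell is demoted to debris with a
reason flag.

**Constriction.** The waist search is restricted to the central 80% of
the arc length and to *local minima* of the width profile — a monotone
taper running into the window from an end-cap is not a waist. The degree
is `1 - w_min / median(flanking width)`, flanking = interior vertices
more than 0.5 µm from the waist (so the septum's own shoulders do not
deflate the reference). When the image is available — always, in the
pipeline — widths come from subpixel intensity profiles: the distance
between the half-depth crossings of the perpendicular intensity profile,
depth measured against a large-scale background estimate. For a blurred
dark body the half-depth crossing sits at the true edge, making this
estimator insensitive to the ±1 px boundary jitter of a thresholded mask;
on fixtures it recovers a generated depth of 0.5 to about ±0.08, where
mask-EDT widths saturate near 0.4 and mislabel noisy rod boundaries. A
cell is predivisional (PD) iff the degree reaches 0.25 — a threshold with
a wide stable band on fixtures (uniform rods measure < 0.2, generated
septa ≥ 0.35).

**Stalk-pole assignment.** Each kept stalk is assigned to the cell pole
nearest either skeleton endpoint, if that distance is ≤ r_max = 0.5 µm;
ties break by (distance, cell id, pole1). Unassigned is a valid outcome;
removed stalks are never assigned.

**Final typing.** The object classifier is authoritative for stalked vs
swarmer; the constriction call splits stalked into ST and PD under the
three-class scheme (the two-class scheme collapses PD into stalked, the
reading used for stalked:swarmer ratios). Debris never enters a
denominator.

## Population statistics

Replicate-level summaries carry per-type counts, the counted total
(debris excluded) and the stalked fraction (ST + PD over counted).
Measurement vectors can be subsampled without replacement to fixed sizes
(e.g. 450 cells for length, 300 for stalk length), seeded; undersized
groups are returned whole with a flag. Significance testing is one-way
ANOVA (F = (SSB/dfB)/(SSW/dfW)) followed by all pairwise pooled-variance
t tests (Welch by option) with Bonferroni correction — adjusted
p = min(1, m·p) — at alpha = 0.05. Proportions are compared on
per-replicate fractions, not pooled counts. Zero within-group variance
with equal means yields an explicit degenerate result rather than a
division by zero. Null calibration (1000 seeded simulations) is part of
the test suite.

## Validation protocol

Predicted objects are matched to reference annotations (expert tables, or
generator truth recast as an annotation) by greedy nearest-neighbour
pairing of reference points under 1.0 µm, each reference used at most
once, exact ties to the lower object index; unmatched objects on either
side are counted and reported, never silently dropped. Confusion matrices
cross-tabulate matched label pairs over {Swarmer, Stalked, Debris}
(predivisional collapses into Stalked, as only stalk presence is visible
to an annotator at this resolution); the headline accuracy restricts the
matrix to Swarmer/Stalked because the debris boundary is subjective.
Matching is needed here (unlike annotating a model's own objects) because
predictions and truth are generated independently; 1.0 µm is comfortably
below the ≥ 2 µm centre-to-centre spacing the generator enforces.

## Reference evaluation and problem sizes

The packaged protocol trains on 20 mixed-condition fields (10
exponential, 4 C/N-starved, 6 P-starved; ~60 cells each at full 2048²
scale), evaluates on 20 held-out exponential-mixture fields, and
estimates the stalked fraction on 10 fields drawn from a 70%-stalked
population (~200 cells per field, ~2000 total). These sizes give roughly
a thousand matched test objects — enough that the pass thresholds
(restricted accuracy ≥ 0.95, fraction error ≤ 0.03, PD sensitivity
≥ 0.90) sit many standard errors from their expected values — and the
whole protocol runs in well under half an hour on one core.

## What the synthetic benchmark shows — and does not

Passing on synthetic data demonstrates that the pipeline's machinery is
correct and well-calibrated under a realistic noise and optics model
with known truth: segmentation recovers geometry, the classifiers
separate the classes the generator renders separable, morphometric
estimators are unbiased at the stated tolerances, and the statistics are
exactly what they claim to be. It does not certify performance on real
micrographs: the generator omits overlapping cells, holdfast and stalk
crossbands, fluorescence bleed, coverslip gradients beyond a linear
shading term, and the full subjectivity of the debris boundary; its
capsule-with-arc geometry is a convention, not a measured shape model.
The mid-90s restricted accuracies on real expert-annotated images are the
motivating regime for the synthetic thresholds, not a claim this package
reproduces from real data.

## Known limitations

- 2-D only; no time lapse, no fluorescence channels.
- Watershed splitting beyond the h-maxima rule is out of scope; heavily
  overlapping cells should be curated as debris.
- Very deep constrictions (depth > ~0.75) can split at segmentation and
  be counted as two cells; the generator's PD depth distribution keeps
  this rare.
- The stalk keep/remove rules are explicit proxies for a subjective
  curation step, not a reconstruction of any particular curator.
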