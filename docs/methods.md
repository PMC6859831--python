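# Methods

## The measurement problem

OCT angiography renders depth-segmented en-face maps of retinal and
choroidal perfusion. Quantitative indices derived from them — total
flow-void (FV) area of the choriocapillaris, vessel density (VD) and
foveal avascular zone (FAZ) area of the superficial and deep capillary
plexuses (SCP, DCP) — are only useful as biomarkers if their test–retest
variability is known. The acquisition model here is two back-to-back
scans of the same eye in one visit, same operator and device, without
repositioning: the second scan images the same scene under a small
translation with fresh noise. This package implements the two
quantification pipelines and the agreement statistics, and validates
them end-to-end on synthetic cohorts with known ground truth.

## Standardization and quality control

Every slab is standardized before quantification by percentile contrast
stretching: the affine map sending the (1st, 99th) intensity percentiles
of a centered reference square (half the image side) to (0, 255), clipped.
Percentile rather than min–max anchoring guards against isolated hot or
dead pixels; the central reference square makes the map insensitive to
vignetting at the field edge. A zero-spread reference square (constant
image) leaves the image unchanged with a warning. The map is idempotent
and invariant to affine re-lighting up to one intensity level.

Scans are excluded when the device signal strength is below 7/10, when
the motion score exceeds a threshold (default 0.1), or when a manual
floater flag is set in the manifest. The motion score is the fraction of
adjacent row pairs whose Pearson correlation falls below 0.2 — a
quantitative proxy for horizontal motion artifacts, which appear as rows
decorrelated from their neighbours. The cutoff 0.2 was chosen so that
noise-free synthetic capillary texture scores 0 while injected random
rows are flagged; real-cohort use should re-tune it against a graded
sample. Floater detection is a manual flag, not automated: the defining
evidence (a large void absent from the consecutive scan) needs human
review of the pair.

## Choriocapillaris flow voids

Per scan pair: (1) standardize all slabs; (2) binarize the SCP slab by
Otsu's method and use the vascular pattern as an overlay marking likely
projection artifacts in the CC slab; (3) rescale the intensities of
overlay-flagged CC pixels with the affine map that matches the mean and
SD of the unflagged pixels; (4) register the two CC slabs by exhaustive
integer-translation normalized cross-correlation (NCC); (5) crop both
CC and avascular slabs to the overlap; (6) per scan, threshold at
T = mean + 1.96·SD of its own cropped avascular slab (population SD;
at ≥10⁵ pixels the sample/population distinction is negligible, but one
form must be fixed for bit reproducibility); (7) count CC pixels with
intensity ≤ T (inclusive, per the definition of the deficit threshold)
and convert by the pixel footprint (extent/grid)². No minimum-region
filtering is applied: the statistic is total FV.

Design notes:

* **Artifact correction.** The correction is specified only as raising
  intensities in artifact regions. A purely multiplicative mean-matching
  rescale is the minimal such map, but it scales the noise by the same
  factor: when standardization has pushed the artifact population near
  zero (which happens when the reference square contains almost no dark
  pixels, e.g. at very low void fractions), the required gain is large
  and the amplified noise spills bright pixels below T, inflating FV by
  several percent of the slab. The implemented map matches both the mean
  and the SD of the unaffected region; the mean-matching contract is
  preserved and the correction is gain-stable. Dark (flow-void) pixels
  under artifacts remain below threshold; genuinely shadowed flow under
  an artifact is unrecoverable by any intensity map and is not modeled.
* **Registration** is translation-only (no rotation/scale), searched
  exhaustively within ±max_shift (default grid/10) with ties broken by
  smallest |dx|+|dy| then lexicographic (dx, dy); sufficient for
  non-repositioned same-visit scans. The NCC surface is evaluated
  exactly via an FFT cross-term plus integral-image overlap sums —
  algebraically identical to the naive per-shift loop. An overlap below
  25% of the frame at the best shift raises an alignment error.
* **T after cropping, per scan**: the threshold is recomputed on the
  cropped avascular slab of the same scan, so both measurements of a
  pair share the analyzed area but keep their own noise floor.

## Vessel metrics

Standardize → Otsu global threshold (256-bin between-class variance,
ties to the lowest threshold; brighter class = vessel regardless of
display polarity) → TVA = vessel pixels × footprint → VD = TVA / area →
FAZ. DCP slabs are processed without artifact removal, mirroring the
protocol choice not to correct DCP projection artifacts. Global (not
local/adaptive) Otsu is deliberate: it is the named protocol step, with
the known cost of sensitivity to non-uniform illumination.

FAZ area supports two modes. Manual polygons (the faithful analogue of
operator tracing) are measured by the shoelace formula. The seeded
automatic mode closes the vessel mask with a 2-px disc (bridging 1-px
capillary gaps that would leak the fill) and 4-connected flood-fills the
avascular region from the seed. `jittered_faz_polygon` simulates
operator tracings — vertices of the true FAZ boundary perturbed by a 5%
radial SD — giving manual-mode measurements a realistic nonzero
repeatability coefficient where the automated indices have exactly zero.

VD is reported both as a fraction and as TVA in mm²; published summaries
of this protocol tabulate the mm² form (a 9 mm² constant divisor apart,
the two carry the same ratios), so agreement reports use TVA in mm².

## Repeatability statistics

Differences are d = scan1 − scan2 (fixed direction for sign
reproducibility), SD of differences is the sample (n−1) form, CR =
1.96·SD(d), limits of agreement bias ± CR, and the bias test is a
two-sided one-sample t-test of d against 0. ICC(3,1) is computed from
the two-way ANOVA decomposition, ICC = (BMS−EMS)/(BMS+EMS) for k = 2,
with the exact F-based (Shrout–Fleiss) 95% CI; it estimates
between-subject variance over between-subject plus measurement variance,
and is cross-checked in the tests against an independent from-scratch
ANOVA oracle and against `pingouin`. CV uses the duplicate-measurement
within-person SD, √(mean d²/2), over the grand mean, on the raw (not
log) scale. Bland–Altman's CR/mean ratio complements the ICC: ICC can
look excellent in a heterogeneous cohort even when the absolute
repeatability margin is a third of the mean measurement.

## The synthetic cohort generator

What it emulates: paired same-visit acquisitions (a 6×6-mm CC
acquisition with CC, SCP and avascular slabs; a 3×3-mm plexus
acquisition with SCP and DCP), per-subject true index values drawn with
a stated between-subject SD, per-scan measurement error with a stated
within-subject SD realized through the image construction itself, a
known integer inter-scan translation (scenes are built on a padded
canvas and windowed), projection artifacts injected into CC slabs along
the SCP vascular pattern, and additive Gaussian pixel noise clipped to
[0, 255].

Construction: vessel networks and flow-void patterns are rank-thresholded
smoothed noise fields (band-pass for capillary texture, plus drawn
branching curves for larger vessels), so the selected pixel count is
exact to one pixel and sets at different fractions are nested — the two
scans of a pair differ by toggling a small pixel set rather than by
independent scenes, keeping them spatially correlated so registration is
meaningful. The FAZ is an avascular disc ringed by a boosted annulus of
vessels (the perifoveal anastomotic arcade), which gives the seeded
flood fill a closed border. The avascular slab is a low background with
a sparse bright-speck tail, so that after its own standardization its
mean + 1.96·SD lands between the CC deficit and flow levels — the
property the threshold relies on in vivo. All randomness descends from
one integer seed through per-subject spawned streams; cohorts are
bit-reproducible.

Default study conditions mirror the published 85-eye uveitis cohort
summary: CC FV mean 1.16 mm² [SD 1.88] and CR 0.401 mm² on the 36 mm²
slab (fractions 0.0322 / 0.0522 / 0.0040 for mean / between-SD /
within-SD), SCP and DCP VD and FAZ means and SDs converted the same way.
The between-subject draw is truncated (redraw, fallback clip) to keep
fractions in [0.002, 0.6]; the published summary gives no distributional
form, so the normal-with-truncation choice is the generator's own, and
the recorded "true ICC" (between²/(between²+within²)) refers to the
untruncated SDs. Intensity levels (background 40, vessel 200, CC deficit
50 / flow 180, artifact depth 60) are fixed rendering constants chosen
to give the modes a comfortable separation relative to the default noise
SD of 5.

What it does not emulate — and what passing tests therefore do not
show: OCT speckle and flow decorrelation statistics, segmentation errors
between slabs, rotation or torsion between scans, non-uniform
illumination, real choroidal shadowing. Ground-truth recovery here
demonstrates the algorithmic contract (thresholds, masks, geometry,
statistics), not device-level accuracy.

## Problem sizes and numerics

Tests and the acceptance script run the image stages at 256² (512² where
the contract is about a 512² field, e.g. exact registration of ±20-px
shifts) and the statistical recovery studies at n = 500 subjects × 10
seeds — sizes at which every recovery band is comfortably resolved while
the whole suite runs in well under a minute per stage. Intensities are
processed as float64 in [0, 255] and rounded to 8-bit only at file I/O.
Otsu ties break to the lowest threshold; registration ties break toward
the smallest shift; flood-fill connectivity is 4-neighbour; the NCC
comparison tolerance is 1e-9 (FFT rounding is ~1e-10 of the surface).

## Known limitations

* The intravisit within-subject error is injected at the index level
  (pixel-set toggling); it does not model spatially structured
  acquisition differences such as focal signal dropout.
* The seeded-automatic FAZ needs an enclosing capillary border; on real
  images with a broken perifoveal ring it will leak and the manual mode
  should be used.
* Manifest-level floater flags and the motion-score threshold are
  cohort-tuning points, not validated classifiers.
* Intervisit (between-day) repeatability and subgroup ICC comparisons
  are out of scope.
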