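# Methods

This note documents the models, estimators and numerical choices behind
`zfscreen`, and what the synthetic-data generators do and do not emulate.

## Scope and pipeline

The package reimplements a quantitative zebrafish-larva drug-screening
workflow as a tested library: per-larva cardiovascular measurements
(heart rate, ejection fraction) from fluorescence heart movies, vessel
morphometry (intersegmental vessel count, length, width, area) from
trunk projections, body length, locomotor activity under a programmed
bright/dark cycle, plate-aware nonparametric statistics with median
batch correction and a composite effect score, and a qPCR ΔΔCt stage.
Image acquisition, tracking hardware and learned segmentation weights
are outside the package: a synthetic-data module stands in for them so
that every stage can be verified by parameter recovery.

## Heart quantification

Two routes are provided, mirroring a semi-automated and an automated
analysis branch:

**Kymograph route (heart rate).** The heart is located in the
maximum-over-time projection by Otsu thresholding; nearby bright
components (the two chambers, separated by the dimmer atrioventricular
canal) are grouped by dilation with a disk of radius 15 px before the
largest group is boxed. A vertical line at the center of the ROI's
lower edge, spanning the lower 30 % of the ROI, is sampled in every
frame (1-px steps, linear interpolation) to form a kymograph; beats are
the local maxima of its mean-intensity profile. Peak detection
self-calibrates: the minimum peak separation is half the profile's
dominant Fourier period and the profile is denoised with a moving
average of about one sixth of that period; the prominence threshold is
10 % of the dynamic range. The profile is extended by one
global-minimum sample at its tail so that a beat peaking just inside
the recording window keeps its full prominence; a maximum that lands on
the final sample itself is discarded as undecidable. Heart rate is
reported in beats/min as `n_beats / (n_frames / fps) * 60` — the frame
rate is explicit acquisition metadata and every rate carries this time
base.

**Area-trace route (ejection fraction).** Each frame is segmented by
the reference backend (global Otsu threshold, connected components,
small objects under 50 px² removed); of the two largest components the
upper one is the ventricle, matching the lateral mounting. The backend
is a plug-in point — any callable image → boolean mask (for example a
learned predictor) can replace it. A movie in which any frame lacks a
ventricle is rejected as a whole and propagates as missing values,
never as silent zeros. Diastoles are local maxima and systoles local
minima of the per-frame ventricle area; runs of same-type extrema are
collapsed to the most extreme one so that systole and diastole strictly
alternate. EDV and ESV are the medians over detected diastolic and
systolic areas and

    EF (%) = (EDV − ESV) / EDV × 100.

EF is computed unclipped; out-of-range values raise a data-quality
warning, and an EDV of zero or an unusable trace (fewer than one full
cycle) is an error. Because all areas are 2D projections, the ratio is
unit-free and invariant under spatial rescaling.

Peak-detection defaults elsewhere: minimum distance
`ceil(0.3 × fps / beat_rate_guess)` samples (guess 2 beats/s) and
prominence 10 % of the trace's dynamic range. All detections accept
add/remove index edits — the programmatic replacement for the manual
supervision the original interactive workflow relied on.

## Vessel morphometry and body length

ISVs are counted by sampling an intensity profile along a line drawn
across the vessel band (a z-stack is maximum-projected first) and
counting supervised local maxima; the relative prominence threshold
makes the count invariant to uniform intensity scaling. Segmented ISVs
are measured by second-moment (region-property) analysis: per-object
major axis (length) and minor axis (width), summarized per larva by
medians. The per-larva ISV area is the product of the median width and
the median length. This product-of-medians estimator is deliberate: it
is not the median of per-object areas, which is also reported
(`median_object_area_px2`) for transparency. Body length is the
polyline length through the drawn anchor points (anterior head to
posterior tail) times the pixel size; in mask mode it is the largest
pairwise distance between foreground pixels (computed on the convex
hull, with exhaustive fallback for degenerate masks).

## Behavior

The default protocol is 30 min dark accommodation followed by six
cycles of 10 min dark / 10 min bright — 150 one-minute bins, 2.5 h.
Phase boundaries are half-open `[start, end)` in minutes; a bin belongs
to the phase containing its start. Per larva, medians of velocity,
moving duration and distance are computed for dark and bright phases;
accommodation activity is the median accommodation-phase velocity. The
light-response index is

    ln((v_bright + 0.001) / (v_dark + 0.001)),

with the offset applied to both terms unconditionally so the ratio is
finite and antisymmetric for all non-negative inputs. Mis-tracked
larvae are consumed as an exclusion list (the original exclusion was by
visual inspection); no automatic track-quality classifier is attempted.

## Screen statistics

Each treatment group is compared to the vehicle (DMSO) controls of the
plates on which that compound was tested, with the two-sided
Mann–Whitney U test: the exact permutation null distribution for
tie-free samples of at most 8 per group, otherwise the normal
approximation with tie and continuity correction. Dead larvae carry no
morphology metrics and enter only the mortality rate (mean over
replicates of the percentage dead before imaging); effusion-positive
larvae stay in the metric comparisons.

Batch correction shifts every measurement of an experiment by
(global control median − experiment control median), computed per
metric. This aligns all control medians exactly while preserving every
within-experiment difference; because a treatment group and its
comparison controls share the same plates, the correction does not
perturb the test's null distribution. Correction is on by default and
both corrected and raw analyses are available.

Effect sizes: Hedges g = (mean_t − mean_c)/s_pooled × J with
J = 1 − 3/(4N − 9); relative median difference
(median_t − median_c)/median_c; fold change FC = median_t/median_c and
percentage effect (FC − 1) × 100. The composite score is

    score = −log10(p) × |g| × |relΔ| × sign(relΔ),

reported only when p < α (default 0.05, two-sided, no multiple-testing
correction; a Benjamini–Hochberg switch could be layered on but is not
default, matching the screen design of comparing each compound only to
its own plate controls). The sign convention follows the direction of
the median shift, so increases are positive (green in the heatmap) and
decreases negative (magenta); non-significant cells are masked grey.
The raw triple product of the three signed factors would be positive
for any internally consistent effect, which is why the magnitude ×
sign(relΔ) form is used.

Compounds are allocated to ΔHeart (heart rate, EF), ΔBody length,
ΔVasculature (ISV count/area) or ΔActivity (dark/bright velocities,
accommodation activity, bright/dark ratio) by the family of their
largest-|score| significant metric; ties break in that fixed family
order; compounds with nothing significant form "No significant
effect". Reported percentages are rounded half-up to one decimal.

## qPCR stage

Relative quantification uses the standard 2^−ΔΔCt method with the
amplification efficiency fixed at 2: per sample
ΔCt = Ct_target − Ct_reference (reference gene rps11),
ΔΔCt = ΔCt − mean(ΔCt of the baseline group), FC = 2^−ΔΔCt. The
baseline group's mean ΔCt maps to FC = 1 exactly, and FC is invariant
to any per-sample constant Ct shift. Group-level fold change is the
mean over biological replicate pools (six by default). Groups are
tested against a chosen reference group (spike + vehicle in the
inflammation-panel design) with the same Mann–Whitney implementation;
stars at p < 0.05/0.01/0.001.

## Synthetic data: what it emulates, what it does not

* **Heart movies** — a ventricle rendered as a filled ellipse whose
  area oscillates sinusoidally between ESV and EDV at the configured
  beat rate, an anti-phase atrium scaled by `atrium_scale`, constant
  foreground/background intensities plus optional additive Gaussian
  noise. The waveform starts two frames before the first end-diastole
  so every extremum lies strictly inside the 100-frame window; with
  fps/(2·beat_rate) integral the extrema are sampled exactly. Defaults:
  100 frames, 20 fps (the frame rate is a required, explicit parameter),
  2 beats/s, EDV 3000 px², ESV 1500 px², 192×192 px. True EF is the EF
  formula on (EDV, ESV); the true beat count is the number of diastolic
  maxima inside the window.
* **Trunk projections** — `n_isv` vertically oriented elliptical
  stripes (default length 100 px, width 10 px, spacing 30 px) on a dark
  background. Ellipses rather than rectangles because second-moment
  axis measurement of a rasterized ellipse recovers the configured axes
  to within a pixel at the default width, making the generator's truth
  directly comparable to the region-property measurement.
* **Behavior tracks** — one row per schedule minute with
  phase-dependent mean velocity (accommodation uses the dark velocity),
  Gaussian noise clipped at zero (0.5 mm/min by default), distance =
  velocity × 1 min, and a moving-duration fraction per phase.
* **Screen tables** — per-larva records drawn directly from per-metric
  control distributions chosen to be realistic for 4–5 dpf larvae
  (e.g. body length 3600 ± 150 µm, heart rate 150 ± 12 beats/min,
  EF 55 ± 6 %, 26 ± 2 ISVs), with multiplicative treatment effects,
  additive per-plate batch offsets (0.5 control SD by default),
  Bernoulli mortality/effusion, two replicates of 10 larvae per
  compound and 20 controls per plate (the two vehicle wells).
* **Ct tables** — a constant reference-gene Ct and target Cts offset by
  a base ΔCt of 6 cycles minus log2 of the configured fold change, with
  optional Gaussian Ct noise; six replicate pools per group.

Image noise defaults to zero: heart and trunk assays state their noise
level explicitly per experiment (the recovery checks run both
noise-free and at 5 % of the intensity dynamic range). All generators
are bit-reproducible given config + seed.

What the generators do **not** emulate: optics (PSF, out-of-focus
light), photobleaching, anatomical shape variability, pigmentation,
tracking artifacts, or pharmacokinetics. Passing recovery tests
therefore demonstrates correctness of the measurement and statistics
chain on idealized geometry — not robustness to real microscope data,
for which the pluggable segmentation backend is the intended adaptation
point.

## Problem sizes used in the recovery checks

The bundled verification (`scripts/acceptance.py` and the end-to-end
test suite) uses: 20 movies spanning true EF 20–80 % (noise-free and at
5 % noise); 10 movies with beat rates 0.8–2.6 beats/s chosen so each
window holds an integral number of beats, making the expected count
unambiguous; an exhaustive ISV sweep of 0–20 stripes; 200 random
tie-free Mann–Whitney cases with ≤ 7 values per group against a full
enumeration oracle; a 6-plate screen for the batch-correction
invariant; five all-null screens of 25 compounds × 9 metrics (1125
comparisons) for type-I calibration; and a noise-free qPCR round trip
with fold changes {0.25, 1, 4}.

## Known limitations

* The reference segmentation backend assumes bright objects on a dark
  background with a roughly bimodal histogram; it is a stand-in for a
  learned segmenter, not a competitor to one.
* Ventricle/atrium disambiguation uses relative position (upper =
  ventricle), which presumes consistent lateral mounting.
* The product-of-medians ISV area is a biased estimator of mean vessel
  area when length and width are correlated; it is kept as primary by
  design, with the per-object median area alongside.
* Mortality-rate aggregation treats each replicate equally regardless
  of group size.
* The exact Mann–Whitney route switches to the asymptotic
  approximation in the presence of ties at any sample size.
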