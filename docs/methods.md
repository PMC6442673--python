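# Methods

`casparks` detects and characterizes Ca²⁺ sparks — brief, micrometre-scale
fluorescence transients caused by spontaneous Ca²⁺ release from the
sarcoplasmic reticulum — in confocal line-scan (xt) recordings, and ships a
synthetic-data generator plus the validation metrics used to quantify how
well the detector performs. This note documents the model, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Detection model

A line-scan image is a matrix of photon counts `I[x, t]` (space × time).
After subtracting the detector dark count, the analysis assumes

    I[x, t] ~ Poisson(F0[x, t] + S[x, t])

where `F0` is a baseline fluorescence that varies slowly in time and freely
in space (dye loading and cell thickness vary along the scanned line), and
`S` is the spark signal, localized in both coordinates.

**Baseline estimation.** `F0` is fitted independently for every spatial
position as a cubic least-squares spline in time with uniformly spaced
interior knots (default spacing 5 s, inset half a spacing from the stage
edges). The knot spacing must stay much larger than a spark duration
(tens of ms), so sparks cannot be absorbed into the baseline; it can be
shortened by the user for drifting recordings, or lengthened when slow
transients (e.g. Ca²⁺ waves) should be left out of the baseline. Because
sparks bias the fit upward, the estimate is iterative: fit `F0`, detect
candidate spark regions (below), exclude their pixels, refit. Iteration
stops at a mask fixed point, when the largest relative change of `F0`
drops below `convergence_tol` (default 1e-3), or after `max_iterations`
(default 5); two to four iterations are typical. Excluded pixels are
dropped from the fit, not interpolated. If a row retains too few pixels
for the knot vector, the knots are thinned (ultimately a cubic polynomial
or the row mean), with a log warning.

**Variance stabilization.** The corrected image is
`(I − F0) / sqrt(F0)`; for Poisson counts its noise has approximately unit
variance everywhere, regardless of how bright the baseline is locally.
Fitted baselines are floored at 0.1 counts before the division. A single
global threshold in SD units is then meaningful across the whole image —
this is what makes the detector insensitive to uneven staining. The same
property makes the whole pipeline invariant to a multiplicative gain
applied to the counts: `F0` scales linearly, the corrected image by the
square root of the gain, and all thresholds are SD multiples.

**Segmentation.** The corrected image is smoothed by a median filter and
then a boxcar (uniform) filter, with reflecting edges. With `SD` the
standard deviation of the smoothed corrected stage, a spark is a connected
component (8-connected by default) of pixels above `spark_intensity × SD`
(default 2.0) that (i) contains at least `min_region_px` pixels (default
40) and (ii) contains at least one pixel above `spark_peak_intensity × SD`
(default 3.8) that survives a median filter of the binarized peak mask —
the median filter discards peaks carried by one or a few high pixels. The
region mask itself is deliberately not median-filtered; the minimal-size
rule plays that role. The region peak is the maximum of the smoothed image
within the component (ties resolved to the earliest time, then the
smallest spatial index), and regions are reported in order of peak time.

**Smoothing kernel sizes.** The defaults are `median_size_px = 5`,
`boxcar_size_px = 5`, `peak_median_size_px = 5`. These were calibrated on
full-size synthetic experiments at background SNR 2: they are the smallest
odd kernels at which the 3.8-SD peak threshold falls safely below the
deterministic signal of a 0.45 × F0 spark (so every such spark is found),
detection at 0.3 × F0 succeeds about half the time, and false positives
stay below 0.07 sparks/(s·100 μm). With 3×3 kernels the smoothed image SD
is ≈0.8 (vs ≈0.5 at 5×5) and the peak threshold sits *above* the 0.5 × F0
signal, so detection of moderate sparks would depend on favourable noise.
A default spark is ≈21 px wide and ≈16 lines long at the default
calibration (0.14 μm, 1.53 ms), so 5×5 smoothing does not materially
erode real peaks. All three sizes remain user-adjustable.

## Spark morphology

Each detected region is wrapped in a rectangular ROI (bounding box padded
by half its extent per side, clipped to the stage); the ROI, not the pixel
mask, drives re-analysis, so a user can edit it and refit. Within the ROI
the normalized change `dF/F0 = (I − F0)/F0` is profiled through the peak:
a temporal profile at the peak position and a spatial profile at the peak
line. Each profile is averaged over a band of ±2 pixels *orthogonal* to
its direction: near the peak the spark factorizes into a spatial and a
temporal component, so averaging a few adjacent rows rescales a temporal
profile by <1.5% without changing its shape, while cutting pixel noise by
√5. (Averaging *along* the profile would widen it and flatten the peak;
`band_halfwidth=0` restores raw single-pixel profiles.)

Profiles are fitted with a cubic least-squares regression spline with
interior knots every 5 samples (≈7.7 ms, ≈0.7 μm at default calibration).
The knot grid is anchored at the profile's maximum sample and the anchor
knot is doubled: a spark rises faster than it decays, so its curvature
jumps at the peak, and the reduced continuity lets the spline track both
flanks. On noiseless default sparks this estimator recovers amplitude,
FWHM and FDHM to well within 1%; a roughness-penalized smoothing spline
at the statistically appropriate penalty was rejected because it flattens
the asymmetric peak (≈30% amplitude loss at R = 2 under SNR-2 noise) and
because noise estimated from successive differences is contaminated by
the spark's own gradient. Monotone (shape-constrained) fitting is not
implemented.

Amplitude is the fitted peak of the temporal profile (in F0 units); FDHM
and FWHM come from a bracketed root search of `fit − peak/2` on either
side of the fitted peak, converted to ms/μm. If a half-max crossing lies
outside the ROI the corresponding fit is flagged and the width reported
as NaN; a spark is "not accepted" only when both profile fits fail or the
amplitude is non-positive. Under noise the estimator inherits the known
biases of peak-picking detectors: because the peak is the *maximum* over
the detected region of a noisy image, low-amplitude sparks are reported
somewhat brighter than they are, and their widths somewhat narrower
(the half-max of an overestimated peak is crossed earlier). Both biases
vanish for large sparks and low noise.

## Synthetic experiments

The generator reproduces a photon-counting acquisition: a flat baseline of
`F0_level` expected counts per pixel, plus sparks

    S(x, t) = R · F0 · 2^−[(x/ξ)² + (t/τ(t))²],   τ(t) = τr (t<0) | τd (t≥0)

with ξ = 1.5 μm, τr = 7 ms, τd = 18 ms (FWHM 2ξ = 3 μm, FDHM τr + τd =
25 ms). The default geometry is 512 px × 0.14 μm by 37,000 lines × 1.53 ms
(≈71.7 μm × 56.6 s); at the default spark frequency of 1.5 sparks/(s·100 μm)
this yields exactly 61 sparks, with centres uniform over the image and
amplitudes cycling (in shuffled order) through the 20-value grid
0.05–0.8 step 0.05 plus 1.0, 1.25, 1.5, 2.0. Overlapping sparks are
allowed and all recorded in the ground truth. Each pixel is Poisson
sampled, multiplied by the gain γ = 255/(α + 5√α) with α = F0(1 + max R)
(the 5√α headroom keeps Poisson excursions below 255), rounded half-up and
clipped to [0, 255] — an 8-bit detector. Background SNR (mean/SD of a
spark-free region) is then √F0_level: levels 2, 4 and 16 give SNR 1.4, 2
and 4. Spark profiles are rendered on ±4ξ / −4τr..+4τd windows; the
truncated tail is below 2⁻¹⁶ of the peak.

What the generator does *not* emulate: spatial structure of the baseline
(sarcomeric banding, cell edges), baseline drift or waves, detector gain
noise and pixel-to-pixel offset variation, spark-shape variability, and
triggered (wave/transient) release. Passing the validation therefore
shows the detector performs as designed under idealized Poisson imaging;
on real recordings the iterative baseline handles slow structure, but the
quantitative sensitivity/FP numbers should be re-derived per experimental
series by simulating at the observed SNR.

## Validation metrics

Detections are matched to ground truth one-to-one: a truth spark is a
candidate for a region if its centre pixel lies inside the region's pixel
set, or if the region peak is within 1 μm and 20 ms of the centre
(tolerances chosen from the spark scale ξ, τ); candidates are assigned
greedily by increasing peak distance, centre-inside candidates first.
Matched pairs are true positives; a second detection of the same truth
counts as a false positive. From matched batches:

- **sensitivity** per true amplitude: fraction of truth sparks detected;
- **false-positive frequency**: FPs with estimated amplitude ≥ cutoff per
  (s·100 μm), a non-increasing function of the cutoff;
- **PPV** per estimated-amplitude bin (width 0.05 × F0, bins with >20
  events);
- **morphology recovery**: mean estimated amplitude/FDHM/FWHM per
  (SNR, R) condition with ≥25 detected sparks.

At SNR 2 with default parameters the detector reaches sensitivity 1.0 for
R ≥ 0.45, ≈0.5 at R = 0.3, false positives below 0.07 sparks/(s·100 μm)
with estimated amplitudes confined to roughly 0.4–0.7 × F0, and PPV near
100% above 0.8 × F0 — the numbers `scripts/acceptance.py` recomputes.

## Experiment-level statistics

For pharmacological comparisons the package computes cumulative spark
frequencies above a cutoff amplitude (default grid 0.5–1.5 × F0), the same
restricted to long sparks (FDHM ≥ 25 ms), frequencies of multi-spark
groups (chains in which each successive spark follows the previous by
< 2 s and lies within 1 μm of the *first* spark — repeated release from
one site; a spark belongs to at most one group, earliest start wins), and
FDHM/FWHM distributions for sparks in the 0.8–1.2 × F0 amplitude window
(split at 1.0). Amplitude cutoffs use ≥ uniformly. Hypothesis testing is
out of scope: the tables are exported as CSV for external statistics
tools.

## Storage

Analyses persist in a single-file SQLite database created on first use:
experiments (file name, calibration), stages with their count statistics
(mean, min, max, 0.1% and 99.9% percentiles), serialized detection
parameters, one row per spark keyed by a UUID (so sparks from many
experiments pool safely in one database), and ground truth for synthetic
runs. Foreign keys cascade on experiment deletion; re-saving a file
replaces its previous analysis; a `schema_version` table guards against
reading a database written by an incompatible version. The schema is
plain SQL and portable to a server database; only SQLite is exercised.

## Problem sizes and determinism

Full-size synthetic experiments (512 × 37,000) are used for the
validation batch: the acceptance script and the test suite each analyze
nine of them (three seeds per background SNR 1.4, 2 and 4). One detection
pass takes on the order of a minute on a single core, dominated by the
median filter and the per-row spline fits. All randomness flows through
`numpy.random.default_rng` seeds carried in `SyntheticConfig`; identical
seeds give bit-identical images, and detection itself is deterministic.

## Known limitations

- Kernel sizes and the two SD thresholds interact; the defaults are tuned
  for the default spark scale and SNR ≈ 1.4–4. Very long release events
  (waves) are detected as one large spark or absorbed into the baseline
  depending on the knot spacing.
- The amplitude of *false* positives is a fitted property of noise, so
  the FP amplitude band moves with the morphology estimator; at SNR 2 it
  sits at ≈0.4–0.7 × F0.
- Merged regions: two overlapping sparks above threshold form one
  connected component and one detection; the one-to-one matcher then
  counts one of them as missed. At the default spark frequency this is
  rare (expected well under one pair per experiment) but not impossible.
- Sub-pixel peak localization relies on the profile fits; at SNR < 1.4
  the fitted peak can sit on a noise excursion several pixels from the
  true centre.
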