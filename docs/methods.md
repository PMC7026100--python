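# Methods

This note documents the models, conventions and numerical choices
behind `dyadkit`, what the synthetic data generator does and does not
emulate, and the known limitations.

## Timelines and speech turns

Annotations are integer milliseconds with half-open intervals
`[onset, offset)`, so abutting segments neither overlap nor leave a
gap, and segment arithmetic is exact (no float drift). Trajectories
are indexed in frames; seconds enter only through `fps`.

Turn merging and silence use the boundary conventions as printed in
the definitions they implement: two same-speaker, same-category
segments merge when separated by strictly less than 150 ms of silence;
a joint silence counts when strictly longer than 150 ms. Categories
never merge into each other; residual cross-category overlap within a
speaker (possible in hand-made annotations) is resolved by clipping the
later turn, which makes the occupancy identity
`vocRatio + noiseRatio + pauseRatio = 1` exact for each partner.
Overlap is vocalization overlap: mother other-noise does not count,
infant atypical vocalizations do.

The synchrony window is anchored at the mother-vocalization *offset*:
a response is an infant vocalization onset strictly inside
`(offset, offset + 3000 ms]`. Infant vocalizations already overlapping
the mother turn do not count, atypical vocalizations do not count as
responses by default (configurable), each mother vocalization counts at
most once, and when consecutive mother turns are closer than the
window, an infant onset is attributed to the earliest still-open
window, so one response can never answer two mother turns. These
conventions are deliberate resolutions of ambiguities in the feature's
informal definition; all are centralized in `RunConfig`.

The 16-feature speech roster (counts, occupancy ratios, intervention
ratio, silence, overlap, three synchrony ratios, motherese ratios) is
fixed in `speech.STT_FEATURES`. Motherese-dependent entries are NaN
when no turn carries a motherese label; NaN propagates to the
classifier's imputation step rather than silently becoming zero.

## Hand tracking

The tracker is a bootstrap particle filter (predict / weigh /
resample) with a first-order state: position, velocity, and a boolean
visibility flag per particle. Infant hand motion is dominated by
abrupt changes of direction and speed, so the dynamic model diffuses
both position (default 1.5 px/frame) and velocity (0.6 px/frame²)
rather than assuming smoothness. The observation model is the
Bhattacharyya coefficient between the RGB histogram (8 bins/channel) of
a small patch at the particle position and a reference histogram of the
target color — the standard likelihood for color-blob particle
filters. Invisible-flagged particles ignore the image and receive a
constant occlusion likelihood (0.05); the flag flips with probability
0.05/frame, letting the filter hypothesize disappearance and
reappearance. Resampling is systematic (lower variance than
multinomial) and triggered only when the effective sample size drops
below half the particle count.

The per-frame estimate is the weighted mean of visible-flagged
particles; a frame is reported missing when the visible posterior mass
falls below 0.5 or the best color similarity falls below the
`likelihood_floor` (0.35). On a missing frame a coarse grid-scan
detection runs, and if the target is found, half the cloud is
re-seeded there — the "tracking with detection" element that makes
recovery after long occlusions reliable. Tracking is deterministic
given the config seed. All tracker constants are package defaults, not
values inherited from any particular recording setup; they were chosen
to track an ~5 px blob in 80×80 synthetic frames with noise SD 8 and
are exposed in `TrackerConfig`. Only 2D tracking is supported; no
stereo reconstruction is attempted.

Normalization divides coordinates by the measured length of a fixed
reference object over its canonical length, making descriptors
comparable across camera zooms.

## Motion descriptors

Descriptors are computed over *visible* frames only. Derivatives use
`numpy.gradient` (central differences in run interiors, one-sided at
edges) inside maximal runs of consecutive visible frames — a dropped
frame breaks a run even when the file omits the row — and nothing is
differentiated across a gap. Coordinates are smoothed beforehand with
a centered moving average (default 5 frames = 200 ms at 25 fps) to
suppress pixel jitter; the window is configurable, and the analytic
unit tests set it to 1 because a moving average attenuates genuine
signal (≈ 6% at 1 Hz) that those closed-form checks measure.

Curvature uses the plane-curve formula with the same finite
differences; the two samples at each run edge are dropped (one-sided
second derivatives are first-order only), and samples with speed below
a floor are excluded — curvature of a near-stationary point is
numerically meaningless. The floor defaults to the pause threshold.

The pause threshold is scale-free: 2% of the trajectory's own maximum
smoothed speed (an absolute threshold can be configured). A trajectory
with zero maximum speed is treated as one long pause rather than zero
pauses. A pause is a maximal sub-threshold run of at least 4 s that
does not span a visibility gap; `pauseRelTime` divides by the time over
which speed is defined. `movementUnitCount` is the number of maximal
supra-threshold runs. The farthest-pair distance is exact: brute force
up to 2000 points, convex hull first beyond that.

The 21-descriptor roster (`motion_features.MOTION_FEATURES`) fixes the
summary statistics as mean/SD/max for speed, acceleration and
curvature plus the pause and space families; the mean-based entries
are included by design choice where only SD and max are canonical.

## Motherese detector

MFCCs: 25 ms Hamming windows, 10 ms hop, 26 triangular mel filters,
orthonormal DCT-II, 13 coefficients. F0: normalized autocorrelation on
40 ms frames with parabolic peak interpolation, search range 60–500 Hz,
voiced when periodicity > 0.5 and frame energy clears 5% of the
segment maximum. These extraction constants are package defaults; the
classifier design (two GMM streams with M = 12 and 15, fusion weight
λ = 0.4, decision at fused score 0 under equal priors) is the model
this package implements. λ weights the segmental stream. Segmental
scores average per-frame log-likelihood ratios so segment duration does
not dominate the fusion; when one stream is missing (e.g. no voiced
frame), the weight renormalizes onto the other, with a logged warning.

The GMM is diagonal-covariance, fit by EM with k-means initialization,
a 1e-6 variance floor, and termination at relative log-likelihood
change < 1e-6 or 200 iterations; the recorded likelihood path is
checked monotone in tests. Suprasegmental vectors are z-scored with
training statistics before GMM fitting since their components differ
by orders of magnitude.

ICC is the two-way random-effects, absolute-agreement, single-rater
form ICC(2,1), computed from mean squares with the F-distribution
confidence interval; absolute agreement (not consistency) is the
appropriate form for rater-vs-classifier validation because it
penalizes systematic shifts. The form choice is a package decision
where the validation design left it open.

## Outcome classification

Missing features are imputed with training-fold means and z-scored
with training-fold statistics; zero-variance features pass through
with SD 1. PCA keeps the smallest number of components reaching the
variance budget (default 95%), with a deterministic sign convention
(largest-magnitude loading positive). The decision stump searches all
features × midpoint thresholds × polarities for minimal 0–1 training
error, with ties broken toward lower feature index, lower threshold,
then the "greater" polarity — fully reproducible. Single-class
training data yields the constant majority classifier.

Under leave-one-out, imputation, standardization, PCA and the stump
are refit on every fold's n−1 rows; fitting PCA once on the full table
is available as `pca_outside_loo=True` to mimic protocols that do not
guard against this leakage, and `drop_incomplete=True` drops dyads with
missing features instead of imputing. The stump classifies in PCA
space (matching the pipeline order), while the feature-ranking table
uses raw features (matching how best-feature tables are reported); raw
p-values are reported with a Benjamini–Hochberg column for reference.
Alternative classifiers can be evaluated by replacing `fit_stump`; the
stump is the only bundled, tested model.

## Synthetic data: what it does and does not emulate

The generator's defaults are the study conditions: cohorts of
19 TD + 22 WS− + 10 WS+ dyads, 180 s audio timelines, 60 s trajectories
at 25 fps. Timelines are renewal processes (exponential inter-onset,
exponential durations floored at 200 ms); after each mother
vocalization an infant response onset is placed uniformly in the 3-s
window with probability `p_sync`; independent infant vocalizations
arrive on top; same-speaker overlap is resolved by truncating the
earlier event. No generative model is prescribed by the analysis the
package implements; the renewal process is the simplest process
exposing the rate/duration/synchrony structure the features measure.

Group effect sizes are free parameters of the generator, not estimates
of real effects: only their *signs* follow the reported correlations
(WS+ infants vocalize less and answer less than WS−; WS groups move
less vigorously and pause more than TD). Defaults put the pipeline in
a strong-signal regime in which leave-one-out accuracy at n = 51
reaches ≥ 90% — a design goal of the generator, stated in
`DEFAULT_GROUP_PARAMS`, so that end-to-end discrimination is testable;
passing those tests demonstrates that the pipeline transmits a planted
group difference, not that real groups are separable at that level.

Trajectories are first-order random walks on the unit scene box with
reflecting borders (descriptors stay scale-comparable), velocity
redraws at 0.08/frame, and planted pause and occlusion episodes.
Pause episodes dwell at least 4.5 s before an exponential tail that
preserves the requested mean duration: episodes are planted to be
individually detectable against the 4-s pause floor, so the planted
rate is a recoverable ground truth (an untruncated exponential with a
6 s mean would leave about half its episodes below the floor, making
"pauses per minute" unrecoverable by construction). Episode counts
are preserved under collision by rejection placement.

Recovery tests for `p_sync` set the background infant vocalization
rate to zero: with background chatter, chance onsets land in response
windows and the synchrony ratio estimates
`p + (1−p)(1−exp(−rate·window))`, not `p`. The estimator is unbiased
for the response channel in isolation, which is what those tests
check.

Speech segments are harmonic stacks with prosody-controlled F0
contours — not remotely realistic speech. The motherese classes are
separated by construction (F0 mean ≈ 280 vs 190 Hz, wide vs narrow
modulation, brighter vs darker spectrum), so near-perfect held-out
accuracy on this corpus validates the feature/classifier plumbing, not
performance on real infant-directed speech. Videos are a uniform disk
on Gaussian noise: no lighting changes, skin-colored distractors, or
motion blur. None of the generators model clinical covariates.

## Problem sizes

Default test and acceptance runs use: 51-dyad cohorts; 100 replicate
trajectories for pause-rate recovery; ~1000 mother vocalizations for
`p_sync` recovery; a 60-per-class training corpus and 100-per-class
held-out corpus for the motherese ICC; three 20-s videos (1500 frames)
for tracking quality. These sizes put Monte-Carlo standard errors well
inside the asserted tolerances while keeping a full run under a
minute.

## Known limitations

* The tracker is tuned for a high-contrast colored blob; real video
  (lighting, similar-colored objects, motion blur) would need a richer
  observation model and is out of scope.
* EAF support is a read/write subset (tier per speaker, value =
  category); full ELAN semantics are not implemented.
* The stump-on-PCA classifier is intentionally minimal; with tens of
  dyads, anything richer overfits, but the plug-in point is there.
* Feature-level p-values are reported raw (with a BH column); with 37
  correlated features they are descriptive, not confirmatory.
* `pauseMeanDur_s` is 0 (not NaN) when no pause exists, so that pause
  totals remain summable across dyads.
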