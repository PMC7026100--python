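# dyadkit

Behavior and interaction imaging for mother–infant dyads: a tested,
reusable implementation of a multimodal social-signal-processing
pipeline for early developmental risk assessment, together with a
synthetic dyad generator so every stage runs without clinical
recordings.

## The problem

Infants at high neurodevelopmental risk — the motivating case is West
syndrome, an infantile epileptic encephalopathy in which a subset of
children later develop autism spectrum disorder and/or intellectual
disability — may already show subtle differences in how they move and
how they engage vocally with their mothers during the first year of
life. Quantifying those differences requires instrumenting an ordinary
play interaction: tracking the infant's hand in video, segmenting who
vocalizes when, measuring how promptly the infant answers the mother,
and classifying the mother's speech register (motherese vs ordinary
speech). `dyadkit` implements that measurement chain and the
classification analysis on top of it, for researchers in developmental
psychiatry and social signal processing.

## What the package computes

**Hand movement (vision channel).** A bootstrap particle filter with a
first-order dynamic model (position + velocity, Gaussian diffusion)
tracks a colored wristband through video frames at 25 fps; a boolean
visibility variable in each particle's state handles occlusion, so
frames where the hand is hidden come out as *missing coordinates*
rather than hallucinated positions. A 60-s analysis window (1500
coordinate pairs) is chosen to maximize hand visibility, and
trajectories are rescaled by a fixed reference length to remove camera
zoom. From the normalized trajectory, 21 descriptors are computed:
coordinate ranges and SDs, the exact farthest-pair distance, path
length, speed and acceleration summaries (central finite differences
inside maximal visible runs, never across gaps), plane-curve curvature

    kappa = |x'y'' − y'x''| / (x'^2 + y'^2)^(3/2),

and movement pauses — intervals of at least 4 s with speed below a
threshold (default 2% of the trajectory's own maximum smoothed speed).

**Speech turn taking (audio channel).** From an annotation timeline
(speaker, category, onset, offset), speech *turns* are maximal vocal
streams containing no silence of 150 ms or more. Sixteen features
follow: vocalization/noise/pause occupancy ratios per partner, joint
silence (> 150 ms), overlap ratio, and the synchrony ratios — the
fraction of mother vocalizations answered by an infant vocalization
onset within 3 s of the mother turn's offset, overall and split by
motherese.

**Motherese detection.** Mother vocalizations are scored by two GMM
classifiers — segmental (13 MFCCs, M = 12 diagonal-covariance
components per class) and suprasegmental (F0/energy/duration
statistics, M = 15) — fused as `λ·segmental + (1−λ)·suprasegmental`
with λ = 0.4. An ICC(2,1) utility validates classifier-vs-rater
agreement.

**Outcome classification.** Dyad feature tables are mean-imputed,
z-scored, reduced by PCA (smallest k reaching 95% explained variance)
and classified by a decision stump (single feature, single threshold,
exhaustive 0–1-error search) under leave-one-out cross-validation, with
all preprocessing refit inside each fold. Point-biserial Pearson
correlations of each raw feature with the class, ranked by |r|,
reproduce the "best features" analysis. The arithmetic helper
`accuracy_from_counts` turns error counts into percentages: 12 errors
among 51 dyads is 76.47%, 6 among 32 is 81.25%.

**Synthetic dyads.** Timelines come from a renewal process with a
controllable probability `p_sync` that the infant answers within the
3-s window; trajectories from a first-order random walk with planted
pause episodes, abrupt velocity redraws and occlusion gaps; videos as a
colored disk on a noisy background; speech segments as harmonic signals
with motherese-like (high, strongly modulated F0) or flat prosody.
Cohorts follow the 19 TD / 22 WS− / 10 WS+ study layout, with group
effects matching the reported correlation signs (WS+ infants vocalize
less, answer less, move less, pause more).

## Worked example

```python
from dyadkit import CohortSpec, make_cohort, classify_cohort

cohort = make_cohort(CohortSpec(seed=7))        # 19 TD + 22 WS- + 10 WS+
res = classify_cohort(cohort, mode="ws_vs_td")
print(res.summary(top=5))
```

prints

```
Dyad outcome classification (decision stump, leave-one-out)
============================================================
dyads: 51    classes: TD vs WS
PCA components kept: 12 (variance budget 0.95)
LOO accuracy: 98.04%

confusion matrix (rows = true, cols = predicted)
                    TD        WS
          TD        19         0
          WS         1        31

top features by |point-biserial r| (class 1 = WS)
feature                         modality               r         p
accMean                         Video, infant      -0.87  1.27e-16
accSd                           Video, infant      -0.86  3.94e-16
velMax                          Video, infant      -0.85  3.21e-15
pathLength                      Video, infant      -0.84  1.77e-14
velMean                         Video, infant      -0.83  5.43e-14
```

The confusion matrix shows one WS dyad misclassified as TD out of 51;
the feature ranking says the synthetic WS groups are separated above
all by how vigorously the infant's hand moves (negative r: lower
acceleration and velocity in the WS groups), mirroring the kind of
feature table this analysis produces on real cohorts. With
`mode="wsplus_vs_wsminus"` the same machinery contrasts the two WS
subgroups, where vocalization counts and synchrony ratios carry the
signal.

The command-line interface mirrors the pipeline stages: `dyadkit
simulate`, `track`, `extract-motion`, `extract-audio`, `classify`,
`report` (see `dyadkit --help`).

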