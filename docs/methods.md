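# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `latemp`, and what the synthetic benchmark does and does not show
about real recordings.

## The scientific question and the data model

The pipeline targets block-designed emotion-induction studies in which
tympanic membrane temperature (TMT) and wrist skin temperature are recorded
bilaterally at 20 Hz. The quantity of interest is the right-minus-left
temperature difference over time: the hypothesis under test is that emotional
valence shifts right–left TMT (negative emotions lowering it relative to
positive ones) while a peripheral site such as the wrist shows no such
lateralization. The default study design is 10 participants × 2 experiments,
each experiment containing four emotion blocks (fear, sadness, joy, love;
joy/love positive, fear/sadness negative) of two 120-s labeled segments —
80 labeled samples per temperature modality per experiment.

## Synthetic-data generator

Real recordings from such studies are typically unavailable, so the
generator emulates the *statistical* structure the analysis assumes, per
participant `i`, experiment, site and 1-Hz time index `k`:

```
diff_i(k) = b_i + W_i(k) + s * e(k - k_segment) + z_i(k)
left_i(k) = B_i + V_i(k)
right_i(k) = left_i(k) + diff_i(k)
```

- `b_i ~ N(0, diff_baseline_sd)` — participant-level right–left offset
  (default sd 0.1 °C);
- `B_i` — site baseline (36.8 °C tympanic, 33.0 °C wrist) plus a shared
  body offset `N(0, 0.3 °C)`;
- `W_i, V_i` — random-walk drifts, innovation sd `drift_sd` = 0.001 °C/s;
- `z_i` — stationary AR(1) noise, lag-1 coefficient 0.8, stationary sd
  `noise_sd` = 0.05 °C;
- `e(·)` — the planted effect: inside `effect_window` (default 70–85 s of
  each segment) every *negative*-valence segment is shifted by
  `effect_magnitude` (default −0.3 °C) on the tympanic difference and by
  `wrist_effect_magnitude` (default 0) on the wrist difference, so the
  tympanic-vs-wrist contrast holds by construction.

The 1-Hz latent series is upsampled by repetition to 20 Hz and white sensor
noise (sd 0.02 °C, the resolution of typical medical infrared sensors) is
added per raw sample — this makes the 1-Hz resampling step consequential
rather than a no-op. Segments are separated by 60-s unlabeled rest gaps
(one also leads the recording), giving 1500 s per channel per experiment.
Optional movement artifacts are step changes of ±`artifact_magnitude`
(default 2 °C) at Poisson onsets persisting 1–3 s.

**Effect shape.** The default onset is a cosine-tapered "smooth-bump"
(`0.5·(1 − cos 2πτ/W)`), not a boxcar. A 0.3 °C change arriving within one
second is physically indistinguishable from a movement artifact, and the
5-σ cleaning rule below would (correctly, by its own logic) remove it; a
gradual onset is also the physiologically plausible behavior of a
temperature signal. The boxcar shape remains available and is used in tests
of the generative arithmetic.

**Ratings.** Each sub-block also yields self-report ratings on eight 1–9
items; the target-congruent item (tenderness for love, otherwise the
emotion's own item) is drawn around 7.5, same-valence items around 4.5,
others around 2. These exist solely to exercise the rating summary and are
not calibrated to any real rating distribution.

All draws flow from a single `numpy` `SeedSequence`, spawned per participant
and experiment, so identical `(design, effects, seed)` gives bit-identical
datasets and the two experiments of one participant share baselines and
block order but not noise.

## Preprocessing

Per channel: (1) mean over non-overlapping 1-s bins (trailing partial second
dropped); (2) first differences `d[k] = x[k+1] − x[k]` over the
participant's *entire* channel; (3) `d[k] ← 0` where `|d[k] − μ| > 5σ`
(sample sd, single pass, no re-estimation); (4) reintegration from the first
1-Hz sample. The statistics are per participant per channel — the finest
grain consistent with computing them "for each participant". When nothing is
flagged the reconstruction is the exact identity (reintegration inverts
differencing bit-for-bit).

Two limitations are inherent and tested rather than hidden:

- a flagged difference discards the *clean* increment underneath it, so
  recovery after an artifact is exact only up to those lost increments, and
  a spike edge that falls inside a 1-s bin can leak a sub-threshold step
  (≤ 5σ) that persists for the rest of the channel (the reconstruction is
  anchored at the first sample);
- the 5-σ floor is computed on the contaminated series, so it assumes sparse
  artifacts. At roughly ≤ 0.3 % of samples affected the floor stays near the
  clean-noise level; the recovery tests therefore use 0.001 spikes/s
  (~0.2 % of samples). Denser contamination inflates the floor and residuals
  grow accordingly.

## Cluster-based permutation test

Samples are baseline-corrected (first time point subtracted — hence the
statistic at `k = 0` is identically degenerate and reported as 0), averaged
into per-participant condition means `x[i, j, k]`, and tested pointwise:

- valence: paired `t_k = mean(d)/(sd(d)/√n)` on `d_i = x[i,pos,k] − x[i,neg,k]`,
  df = n − 1, two-tailed threshold `t_{0.975}` (2.26 for n = 10);
- emotions: one-way repeated-measures F from the standard partition
  `SS_total = SS_cond + SS_subj + SS_err`,
  `F_k = MS_cond / MS_err`, df = (c − 1, (n − 1)(c − 1)), threshold
  `F_{0.95}` (2.96 for c = 4, n = 10).

Critical values come from `scipy.stats` quantiles, never hard-coded; the
printed 2.26/2.96 serve as regression anchors in tests, and the F
implementation is cross-checked against `pingouin.rm_anova`.

Clusters are maximal runs of consecutive supra-threshold seconds (sign
changes break runs for t; F has one tail); mass is the summed statistic.
The null permutes condition labels independently within each participant —
uniform over the `(c!)^n` relabelings, drawn i.i.d. *with* replacement and
with the identity allowed, matching the convention of "1000 random
permutations" — and records the largest |mass| per draw (0 if none). An
exhaustive mode enumerates the whole space when `(c!)^n ≤ 100 000`; for
c = 2 a relabeling is a sign flip of the paired differences and the whole
null is computed by one vectorized matrix product (the pointwise sum of
squared differences is flip-invariant), which the exhaustive brute-force
oracle test pins to the generic per-permutation path.

Cluster `p` is the plain proportion `#{null ≥ |mass|}/m` — which can reach
exactly 0 — alongside the bias-corrected `(b+1)/(m+1)`, which cannot; the
plain version drives the significance flag, the corrected one is reported
for downstream use. Observed data are not added to the null. Calibration is
verified empirically: over 200 null datasets the family-wise "any
significant cluster" rate falls within the binomial band [0.025, 0.075]
around the nominal 5 %.

## Features and classification

Windows of 20 s at a 10-s stride (11 per 120-s sample), features
[mean, min, max, Shannon entropy] per window concatenated window-major
(44 values). Entropy uses a 10-bin equal-width histogram over the window's
own range, log base 2, with a constant window defined as 0 bits — the bin
count is a free choice exposed in the API since no canonical value exists
for this estimator. Features are computed *without* the cluster test's
baseline correction (min–max scaling absorbs offsets; a flag enables it),
then min–max scaled per feature dimension within participant × experiment ×
site — normalization never sees another participant's data, so
leave-one-participant-out evaluation is leakage-free by construction.
A constant dimension within a scope maps to 0; a single-sample scope is an
error rather than a silent guess.

Classifiers (scikit-learn, hyperparameters pinned): `GaussianNB`
(var_smoothing 1e−9); `SVC` (RBF, C = 0.5, γ = "scale"); `MLPClassifier`
(hidden layers (300, 300, 300), ReLU, adam, lr 1e−3, α = 1e−4, 200-epoch
cap, seeded). Per-participant LOPO accuracies are compared to chance
(0.5 valence, 0.25 discrete) with a two-tailed one-sample t, df = n − 1;
`sd = 0` yields t = 0 (at chance) or ±∞ (off chance) by convention.

**A caution the tests encode:** selecting the best of several classifiers
and then t-testing the winner is anti-conservative. On null (wrist)
channels this select-then-test procedure flags roughly 15 % of synthetic
datasets as "significantly above chance" — the mirror image of the
significantly-*below*-chance wrist results such analyses occasionally
report. The acceptance tests therefore assert the tympanic-vs-wrist
contrast in aggregate across datasets rather than demanding any single null
dataset be non-significant.

## What the benchmark does and does not show

Passing tests demonstrate that the statistical machinery is correct and
calibrated (oracle-exact permutation p-values, nominal Type-I rate, monotone
power, leakage-free decoding at chance on null channels) and that the
pipeline recovers effects of the planted form. The generator encodes only
the analysis's assumptions: it does not model true thermophysiology
(hypothalamic blood flow, ambient coupling, sensor drift with contact
pressure), inter-emotion differences beyond valence, or realistic rating
behavior. Detection at the default −0.3 °C / 0.05 °C noise settings is
essentially certain; nothing here estimates the power of any real study,
and the default magnitudes are free parameters, not claims about real data.

## Problem sizes used by the automated checks

The test suite and `scripts/acceptance.py` run the full default design where
a single dataset suffices (counts, thresholds, feature contracts), 200
single-experiment null datasets for Type-I calibration, 50 datasets for
effect recovery, and 5 datasets for the classification contrast; the
exhaustive-oracle check uses n = 4, c = 2, T = 10 (16 relabelings). These
sizes give binomial error bars comfortably inside the asserted bands while
keeping a full run to a few minutes on one CPU.
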