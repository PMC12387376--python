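# Methods

This note records the models, conventions and numerical choices behind
`respcomplex`, and what the synthetic study conditions do and do not show.

## Signal model of the synthetic generator

A night of breathing is a sequence of valley-anchored breaths. Breath *i*
occupies `[v_i, v_{i+1})` with interval `BBI_i = mean_bbi + ε_i`, where the
Gaussian jitter `ε_i` (SD `bbi_jitter_sd`, default 0.5 s) is clipped at
±40% of `mean_bbi` so every interval stays physiological (clipping rather
than resampling keeps the draw deterministic per seed). The waveform rises
from the valley to the peak over `TI = (1 − te_fraction)·BBI_i` as a half
cosine and decays over `TE = te_fraction·BBI_i` the same way, so the
expiratory fraction of every generated breath equals `te_fraction` exactly
and landmark-based recovery can be scored against it.

The breath amplitude is

```
A_i = base · env_i · (1 + d_i) + ν_i ,
```

with three variability components:

* `env_i = 1 − depth·(1 + cos φ_i)/2`, a raised-cosine periodic-breathing
  envelope. Its phase advances at `2π/envelope_period` (default 60 s, the
  typical waxing–waning period) plus a random-walk increment of SD
  `envelope_phase_jitter` (default 0.45 rad/breath), because real periodic
  breathing is quasi-periodic: its cycle length wanders by tens of percent.
  A metronomic envelope would be *predictable* and would lower, not raise,
  coarse-scale entropy.
* `d_i`, a slow mean-reverting AR(1) amplitude drift (stationary SD 0.25,
  AR coefficient 0.995 ≈ 10 min correlation time at 3 s breaths) present in
  **both** phenotypes. It stands for the gradual tidal-volume variation any
  night shows (posture, sleep stage). It is load-bearing: without a
  correlated component, every amplitude series is dominated by white
  measurement noise and its normalised sample entropy saturates at the iid
  ceiling for *all* subjects, erasing any complexity contrast.
* `ν_i`, iid per-breath amplitude noise (`amplitude_noise_sd`).

The channel signal adds a slow sinusoidal baseline drift (amplitude 0.3,
period 300 s) and white sensor noise (SD 0.1 on the summed signal, i.e.
SNR ≈ 10 against the unit breath amplitude), split 60/40 between the chest
and abdomen channels with independent channel noise. Movement artifacts are
placed as a Poisson process (default 20 bursts/h, exponential durations of
mean 10 s clipped to 0.5–30 s); each burst adds a large low-frequency
transient to the respiration channels and a synchronized 3 Hz, 0.3 g
oscillation plus 0.1 g noise to the accelerometer, so the movement detector
can find exactly what corrupted the respiration. These defaults put the
retained fraction after excision near 0.87–0.92, the regime wearable nights
typically show.

### Phenotype contrast

The non-congested baseline uses `te_fraction` 0.564, envelope depth 0.15
and amplitude noise 0.03. The congestion phenotype adds, per subject drawn
with between-subject spread: +0.027 expiratory fraction (SD 0.03), +0.35
envelope depth (SD 0.10), +0.12 amplitude noise (SD 0.02). Covariates
follow the admission-cohort contrasts: PC subjects are ~6 y older, have
~11 mm Hg lower diastolic pressure, ~0.35 higher log10 NT-proBNP and more
NYHA IV (57% vs 28%). All effects live in a single mapping whose entries
can be zeroed to produce exchangeable groups (used by the null-calibration
tests). These settings were calibrated once, while designing the generator,
so that the congestion group exhibits the qualitative signature the
analysis assumes — longer expiration, higher amplitude-entropy areas at
both fine and coarse scales — and were frozen before the test suite.

What the generator does **not** emulate: apneas and true Cheyne–Stokes
pauses, sleep-stage architecture, position-dependent channel gain, ECG
crosstalk, heavy-tailed interval distributions, or realistic absolute
entropy levels. Passing tests therefore demonstrate that the *pipeline*
recovers what the generator encodes, not that the clinical effect sizes are
reproduced; absolute feature values on real nights will differ.

## Preprocessing conventions

* Night window 23:00–05:00 on the recording's own wall clock; when the
  window crosses midnight the occurrence with the largest overlap is used.
* Movement detection: SD of the accelerometer vector magnitude in 1 s
  windows stepped by 0.5 s, threshold 0.05 g, flagged windows padded by 2 s
  and merged. The threshold sits well below the generator's 0.3 g bursts
  but above its 0.01 g sensor noise.
* Runs shorter than 60 s after excision are dropped: they contribute a
  handful of unstable breaths each.
* Detrending is per-segment ordinary least squares; filtering is a
  5th-order 2 Hz low-pass Butterworth applied forward–backward
  (zero-phase), because breath timing is the measurand and single-pass IIR
  phase lag would bias TI/TE systematically. A single-pass mode exists in
  the configuration for strict literal replication.
* `retained_fraction` is retained duration over the duration of the
  (night-selected) recording.

## Breath segmentation

Peaks and valleys come from prominence-constrained extremum search
(prominence ≥ 20% of the segment IQR, spacing ≥ 0.8 s) run separately for
each polarity and merged; of two consecutive same-type extrema the more
extreme survives (earlier on ties). Each (valley, peak, valley) triple is a
breath, so `BBI = TI + TE` holds exactly by construction. Plausibility
filters: 1 s ≤ BBI ≤ 15 s (4–60 breaths/min) and RA ≥ 10% of the segment's
median RA; dropped breaths are counted and logged, never silently
discarded. Breaths never span an excised gap because segmentation is
per-segment and concatenation is breath-domain.

Boundary note: a ground-truth valley at the first or last sample of a
segment is not a detectable local extremum, so recovery is scored against
breaths whose bounding valleys are interior.

## Sample entropy and MSE

`SampEn(m, r) = −ln(A/B)` with the Richman–Moorman template convention:
both B (length *m*) and A (length *m*+1) count unordered pairs among the
first `N − m` templates, Chebyshev distance, matches at distance ≤ r,
self-matches excluded. `A = 0` or `B = 0` leaves the value undefined and
flagged — no ceiling substitution, because a fabricated large entropy would
masquerade as high complexity. Any summary touching an undefined scale is
itself flagged undefined. The counting kernel is an exact-arithmetic pair
enumeration (numba-compiled, with a chunked vectorised fallback); the test
suite checks its counts against an independent brute-force enumeration.

Two finite-sample facts worth recording: SampEn is only *statistically*
non-increasing in r — with single-digit match counts the conditional
probability A/B is noisy enough to invert, so the monotonicity property is
asserted where counts are stable; and time reversal leaves A exactly
invariant while B can shift by one boundary template's matches under this
convention.

MSE coarse-grains by non-overlapping block means (remainder discarded) at
scales 1–20 with m = 2 and r = 0.2 × the sample SD of the scale-1 series,
held fixed across scales (the original MSE convention; a per-scale r would
erase the white-noise scale decay). Fixing r from the scale-1 SD makes the
curve invariant to rescaling the series, which matters because RA is in
arbitrary units. Curves from series shorter than `20·(m+2)` samples are
flagged low-confidence. Areas use the trapezoidal rule over the scale axis
(`area_1_5` spans 4 scale units, `area_6_20` spans 14; plain summation is
available by configuration), and `slope_1_5` is the OLS slope of entropy on
scale over scales 1–5. Whole-night concatenated series are analysed; the
breath-domain concatenation cannot create spurious templates across gaps
beyond the m−1 junction templates per boundary, which is negligible at
night-scale breath counts.

CVs use the sample (n−1) standard deviation; the instability index uses
linearly interpolated quartiles. The rapid-shallow-breathing index is
relative (RA has no volume calibration), so only its CV is computed.

## Statistics

* Group comparisons: per-group Shapiro–Wilk at α = 0.05 gates Student's t
  (mean/SD summaries) vs Mann-Whitney U (median/IQR); categorical variables
  use chi-square, switching to Fisher exact for 2×2 tables with any
  expected count < 5 (larger sparse tables keep chi-square and carry a
  flag).
* Logistic models are maximum-likelihood fits; odds ratios carry Wald 95%
  CIs. The sequential adjustment sets are {age, sex}, +DBP, +NYHA IV,
  +log NT-proBNP, and all together. Complete separation or non-convergence
  is flagged on the result rather than reported as a number; under
  separation a lightly ridge-penalised refit still supplies predicted
  probabilities (for ROC), while the Wald columns stay undefined.
* ROC AUC is the trapezoidal area, identical to the tie-corrected
  Mann-Whitney statistic; the CI and the p-value against 0.5 use DeLong
  structural components. The operating point maximises Youden's J, ties
  broken toward higher sensitivity — for an inverse predictor (AUC < 0.5)
  this lands on the all-positive corner, and the AUC is printed as
  computed, never flipped. No multiple-testing correction by default; a
  Benjamini–Hochberg switch exists but is off.

## Problem sizes

Simulated nights default to 3600 s (~1100 breaths), which keeps the
coarse-grained series at scale 20 long enough (~55 points) for entropy to
be defined almost always while making repeated-cohort simulation studies
cheap; occasional subjects with an undefined scale are reported as missing
and excluded per-analysis. Monte-Carlo checks in the test suite use 50–200
seeded replicates for calibration properties and 100 replicate cohorts of
30 + 30 subjects for the direction-reproduction study.

## Known limitations

Within-night nonstationarity is modelled only through the AR(1) drift; the
movement detector is a fixed-threshold rule, not a classifier; the
extremum-search reconstruction is prominence-based since the original
algorithm's parameters are not published; entropy absolute levels depend on
the generator's noise decomposition and should not be compared to clinical
values; and the combined logistic model separates perfectly at the default
synthetic effect sizes, so its coefficients (unlike its ROC curve) are not
interpretable there.
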