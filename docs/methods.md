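# Methods

## Problem and scope

Non-traumatic neuro-ICU patients are monitored with continuous scalp EEG
soon after admission.  The package quantifies a ~30-minute stretch of
that recording into a fixed vector of QEEG parameters, combines them
with admission covariates in a Fisher linear discriminant of 3-month
mortality, and compares the resulting classifiers with the APACHE II and
GCS severity scores on ROC terms.  No patient cohort is bundled; a
synthetic-data module generates EEG and cohorts with the statistical
structure the analysis assumes, and all empirical claims below are the
ones the test suite and `scripts/acceptance.py` actually compute.

## Signal path

**Segment selection.** The earliest contiguous segment of the requested
duration (default 30 min) is taken, after an optional settle-in skip.
An optional per-channel amplitude ceiling vetoes grossly contaminated
candidate starts (scanned in 10-s steps); if nothing passes, the
earliest segment is used and epoch-level rejection is relied on.  This
makes segment choice deterministic and auditable.

**Filtering.** 50 Hz notch (second-order IIR, Q = 30, ≈ 1.7 Hz
bandwidth), Butterworth high-pass (order 3, −3 dB at 1 Hz) and low-pass
(order 8, −3 dB at 30 Hz).  All filters are applied forward–backward
(zero phase), which doubles the effective attenuation; zero phase is
standard for QEEG because band power must not be smeared by phase
distortion.  The measured chain attenuates a 50 Hz sine by > 40 dB and a
0.1 Hz sine by > 60 dB while passing 10 Hz within 1%.

**Epoching and artifact handling.** Non-overlapping 10-min windows, each
cut into 60 non-overlapping 10-s epochs; a trailing partial window is
dropped.  Epochs whose peak absolute amplitude on any channel exceeds a
ceiling (default 500 µV) or that contain a flatlined channel are masked
and excluded from every downstream statistic.  When EOG channels are
present, an optional linear regression of EEG on EOG can be applied
first.  This amplitude/flatline rule is a deliberately simple,
deterministic form of ocular/movement artifact control; runs are
labelled with the method in their provenance output.  Adaptive or
ICA-based ocular removal is out of scope.

## QEEG parameters

PSDs come from Welch's method per epoch — 2-s Hamming sub-segments at
50% overlap, giving 0.5 Hz resolution (needed to resolve the 0.5 Hz
delta edge) — averaged over the window's unmasked epochs, density-scaled
so the integral over [0, fs/2] estimates signal variance (verified by a
Parseval check within 5% on white noise).

Band powers integrate the PSD (trapezoid) over half-open bands
δ [0.5, 4), θ [4, 8), α [8, 13), β [13, 20) Hz so adjacent bands never
share a bin.  Total power is the sum of the four band powers, hence the
power rates sum to exactly 1.  Variability is the raw MAD (no 1.4826
consistency factor) over the median of the per-epoch band powers;
MAD/median is unbounded above, so the value is clipped to [0, 1] as the
parameter is defined on that range.  The BSI averages the normalised
left–right difference jointly over homologous pairs and bins (the plain
mean makes the order immaterial), skipping bins with zero total power;
both the 0.5–20 Hz and the 0.5–4 Hz variants are computed.  Mean
amplitude is the per-channel SD of the filtered signal over unmasked
epochs.

**Regularity.** Per 10-s epoch and channel the squared signal is
smoothed into an amplitude envelope by an edge-normalised 0.5-s moving
average, sorted descending into q(1..N), and
`REG = sqrt( Σ i² q(i) / ((N²/3) Σ q(i)) )`.  With the envelope
smoothing a constant-amplitude oscillation gives REG ≈ 1 and a 10%-duty
burst pattern ≈ 0.1; the normalising constant is anchored by the
unsmoothed statistic's closed form √3/N for a single spike among N
zeros (exposed via `smooth_s=0`).  The smoothing window matters: on raw
squared samples even a pure sine yields ≈ 0.63, so the envelope step is
what makes REG a continuity measure rather than a waveform-shape
measure.

**Aggregation.** Channels are averaged (plain mean) within each window
before the subject-level median across windows; a feature missing in
some windows is the median of the remaining ones, and a subject with no
usable window is excluded with a reason.

## Prognostic model

Features are z-scored on the fitting data (training-split medians impute
missing values), and the discriminant is `w = S_W⁻¹(μ₁ − μ₀)` with
`S_W` the pooled within-class covariance.  With 19 features and
80-subject cohorts `S_W` is ill-conditioned, so by default it is shrunk
toward its diagonal with a Ledoit–Wolf intensity estimated on the
class-centred data; shrinkage can be fixed or disabled (a singular fit
then raises, advising shrinkage).  The intercept uses empirical class
priors, so `expit(score)` is the posterior mortality probability under
the equal-covariance Gaussian model.  Feature importance is |w| on the
standardised scale, reported raw and rescaled to max = 100 — the
*ranking* is the deliverable; no published importance scale is assumed.

Cross-validation is stratified k-fold (default 5), with standardisation,
imputation and shrinkage re-estimated inside every training fold;
out-of-fold scores are pooled into a single ROC (per-fold AUCs are also
reported) and fold assignment is reproducible from the seed.  `k ≥ n`
degenerates to leave-one-out.

Two feature sets ship as named configs: `qeeg4` (δ/β/θ/α power rates)
and `full` (the 14 scale-free QEEG parameters plus APACHE II, sex and
the hypertension/CHD/diabetes histories).  GCS and age are excluded from
`full` because APACHE II already incorporates both.  The raw GCS and
APACHE II scores are evaluated directly as single-feature classifiers —
a monotone score needs no refit.

## Evaluation

Scores are oriented so larger = higher mortality risk (positive class =
death); AUCs below 0.5 are reported as-is.  The empirical AUC equals the
mid-rank Mann–Whitney statistic (checked against a brute-force
concordant-pair count).  The operating point maximises Youden's J with
ties broken toward higher specificity; PPV/NPV use the sample
prevalence.  Confidence intervals are stratified nonparametric bootstrap
percentile intervals (default 0.95, 1,000 replicates, seeded).

The DeLong comparison uses mid-rank placement values: per-model
structural components for positives and negatives, their 2×2
covariances scaled by 1/m and 1/n, and a two-sided normal test on the
AUC difference.  Identical score vectors short-circuit to p = 1.  The
implementation is validated three ways: the single-AUC variance against
a brute-force pairwise-comparison oracle, the paired variance against a
10,000-replicate paired bootstrap on a fixed 10-subject instance (within
15%), and the type-I error rate over 2,000 null simulations at n = 200
(within [0.03, 0.07] at α = 0.05).

Baseline tables compare groups per variable: Student's t with mean ± SD
when a Shapiro check (α = 0.05 per group) passes in both groups, else
Mann–Whitney with median (IQR); binaries use Pearson's chi-square
without continuity correction, with Fisher's exact substituted when any
expected cell is below 5 (the common SPSS-style practice with a
small-cell guard).  The bootstrap CI level is a config knob defaulting
to 0.95.

## Synthetic data: what it emulates, what it does not

`gen_eeg` builds each channel as a weighted sum of band-limited Gaussian
noise components (default weights 0.45/0.25/0.20/0.10 — a
delta-dominant, ICU-like profile), with per-epoch log-normal power
jitter, a right/left amplitude ratio for hemispheric asymmetry, and a
continuous or burst-suppression (duty/period) envelope; a sinusoid
carrier mode is kept for analytic tests.  Broadband noise is the default
because real EEG spectra are broadband; the generator does not attempt
biophysical realism (no dipole/forward model, no seizure morphology, no
non-stationary state changes), so passing recovery tests demonstrates
correctness of the measurement chain, not clinical validity.

`gen_cohort` draws outcomes at 33.75% 3-month mortality and features
class-conditionally Gaussian with identity covariance, shifting the
non-survivor mean by δ spread equally along designated informative
features (default: the four power rates, δ = 1.19, so the optimal AUC is
Φ(δ/√2) ≈ 0.80 — the scale of AUC this kind of model reports).
Clinical covariates follow a neuro-ICU case-mix pattern: APACHE II
normal (16, 4) in survivors vs (21, 5.5) in non-survivors, GCS (5.3, 3)
vs (3.9, 2) clipped to [3, 15], diabetes 3.8% vs 33.3%, hypertension
47% vs 63%, CHD 17% vs 30%, male sex 70% vs 33%, age normal (55, 18).
The QEEG feature columns are Gaussian surrogates on an arbitrary scale —
they are not constrained to the physical ranges of the real parameters,
which is irrelevant to the scale-invariant discriminant but means the
generator cannot test range-dependent logic (the signal-level generator
covers that).

## Numerical and design choices

- EDF is written with 1-s records, 16-bit little-endian samples and a
  symmetric physical range with 0.1% headroom; round-trips are exact to
  one quantization step.  Old (T3/T4/T5/T6) and new (T7/T8/P7/P8)
  temporal labels are accepted via an alias table; montage resolution is
  invariant to channel order and case.
- Epochs are non-overlapping: 60 × 10 s exactly fills a 10-min window;
  the 50% overlap applies to the Welch sub-segments within an epoch.
- "Variability all" is the MAD/median of total 0.5–20 Hz power per
  epoch (not an average of band variabilities).
- Zero-denominator cases (flat window, zero delta power, zero-energy
  epoch) propagate as missing values with the window/subject policies
  above, never as exceptions mid-pipeline.
- Analysis artifacts (feature CSV, model JSON, reports) embed a hash of
  the analysis parameters (I/O paths excluded) plus the seed; identical
  config and seed reproduce byte-identical outputs.
- Recovery checks that compare a cross-validated AUC with its designed
  value average three replicate cohorts (n = 2,000 each for δ = 1.19;
  n = 500 for the null): the pooled-CV AUC of a single cohort at these
  sizes has Monte-Carlo SE ≈ 0.011, and averaging replicates compares
  the method's expectation with the design rather than one draw.
- Test and example problem sizes (fs = 250 Hz, 10-min fixtures, 2–4
  electrode pairs) were chosen so the whole suite runs on a laptop-class
  single core in a few minutes; every feature definition is agnostic to
  fs and channel count, and the defaults for real data remain 1,000 Hz,
  19 channels, 30-min segments.

## Known limitations

- The amplitude/flatline rejection is conservative; heavily artifacted
  clinical EEG may need the EOG regression enabled or manual review.
- The 4-QEEG and full feature sets are configs, not discoveries: no
  feature selection is performed in-package.
- The DeLong test assumes the two score vectors cover the same subjects;
  unpaired comparison is not implemented.
- EDF+ annotations are skipped, not parsed; channels with differing
  sampling rates are rejected rather than resampled.
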