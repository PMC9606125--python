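# Methods

`fnirsbci` implements an end-to-end fNIRS brain–computer-interface
analysis for discriminating impulse from non-impulse buying behavior
from prefrontal hemodynamics, together with a synthetic cohort
generator that reproduces the experiment's structure so the whole
chain is testable without recordings. This note documents the models,
the conventions, the parameters that matter, and the limits of what
the synthetic results can show.

## Experimental structure assumed

Two sessions per subject — session 1 is a time-limited discount
(duty-free–style) shopping task designed to elicit impulse buying,
session 2 an ordinary online-shopping control — with 5 trials per
session, each trial 1 s cue + 25 s task + 35 s rest (305 s per
session). Recordings are two-wavelength (780/850 nm) optical density
over 15 prefrontal channels at 8.138 Hz; 30 subjects (13 male / 17
female) by default.

## Montage

15 channels from 5 sources and 7 detectors at 3 cm separation,
channels 1–7 on the right frontal lobe, 8 on the midline, 9–15 on the
left. Only part of the channel→ROI table is fixed by the montage
definition (channels 12/14/15 are left VLPFC; the midline channel is
medial). The shipped default is symmetric:

| ROI | channels |
|---|---|
| DLPFC | 3, 13 |
| VLPFC right | 1, 2, 4 |
| VLPFC left | 12, 14, 15 |
| mPFC | 7, 8, 9 |
| OFC | 5, 6, 10, 11 |

Any assignment beyond the fixed channels is unverifiable from the
montage description alone, so the full table is a config input
(`ProbeLayout.with_roi_overrides`, YAML override file). The 2-D
channel coordinates used for topographic rendering are schematic
drawing positions, not measured optode coordinates.

## Modified Beer–Lambert law

dOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF(λ). With two
wavelengths this is one 2×2 system per channel, inverted in closed
form once (ε, d, DPF are time-invariant); the inverse is exact to
numerical precision, which the round-trip property tests assert at
1e−9 over random well-conditioned extinction tables. Systems with
condition number above a configurable bound (default 1e6) are
rejected with the condition number in the message.

Defaults: ε from the standard compiled molar extinction coefficients
(Prahl's tabulation, omlc.org; 780 nm: 710.04 / 1075.44, 850 nm:
1058.0 / 691.32 cm⁻¹M⁻¹, converted to cm⁻¹µM⁻¹), DPF = 6.0 at both
wavelengths, d = 3 cm. The instrument's true constants are unknown,
so absolute µM values are only as good as these inputs; both are
overridable. A helper converts raw intensity to optical density as
−log10(I/I₀) with I₀ the mean over the first second.

## Filtering

The hemodynamic band of interest is 0.01–0.1 Hz. "4th-order
Chebyshev-II FIR" is self-contradictory as a design description
(Chebyshev type II is an IIR family); the package uses a 4th-order
Chebyshev type-II IIR band-pass applied forward–backward
(`sosfiltfilt`), which honors the order and family while keeping zero
phase so epoch timing is undistorted. A linear-phase FIR variant is
available behind `method="fir"`.

Design details: the stopband edges sit a factor 2.5 outside the
passband (0.004 and 0.25 Hz) with 40 dB single-pass stopband
attenuation (80 dB after the two passes). Measured two-pass response:
−0.6 dB at 0.01 Hz, −0.0 dB at 0.05 Hz, −0.5 dB at 0.1 Hz, −43 dB at
0.2 Hz, −86 dB at 1.0 Hz. The band-edge attenuation and stop factor
are config keys. Filtering is applied to the whole continuous
recording before epoching to avoid per-epoch edge transients; the
filter's impulse response at these corner frequencies is minutes
long, so spectral (FFT) measures — not raw time-domain maxima near
the edges — are the correct way to verify attenuation.

## Epoching and channel means

Epochs span −1…60 s around each task onset: floor(61 s × 8.138 Hz) =
496 samples (8 baseline + 488 task/rest), half-open 0-based sample
intervals throughout. Baseline correction subtracts the −1…0 s mean
per channel; the per-channel temporal mean over 0–60 s (trials
averaged first — the two averages commute) is the unit of all
channel-level statistics. The 60 s window follows the stated analysis
window, anchored at task onset, even though a trial's task phase is
25 s; the window therefore spans task plus rest.

## Features

The trial-averaged epoch (496 × 15) is reduced at each time sample to
five statistics of the 15-channel spatial vector: mean, variance,
slope, kurtosis, skewness — 496 rows × 5 columns per subject-session,
i.e. 74,400 elements for a 30-subject single-session cohort
(496 × 5 × 30). Reading the 496 as seconds is impossible — a session
lasts 305 s — so it is the epoch sample count.
Conventions, stated because the source framework names none:
population (÷n) variance; least-squares slope of value against
channel index 1–15; Fisher (excess) kurtosis; skewness and kurtosis
defined as 0 when the spatial variance is exactly 0. A
sensitivity-analysis alternative (`axis="time"`: the same five
statistics per channel over the 0–60 s window) is available but
cannot reproduce the 496-row decomposition.

Features are min-max rescaled to [0, 1]. The min/max are fit on the
training folds only by default (no leakage of the test fold into the
scaling); `pooled_scaling=True` fits on all rows. Rows outside the fitted
partition may leave [0, 1]; no clipping is applied.

## Classification

Linear-kernel SVM solved by SMO (libsvm through scikit-learn `SVC`),
C = 1.0 fixed — no hyperparameter search, mirroring the protocol's
silence — with an SMO convergence tolerance of 1e−5 for reproducible
decision functions. Rows are pooled within subject across both
sessions (992 rows, binary label = session) and evaluated with
stratified shuffled tenfold cross-validation per subject — one CV
per subject (matching per-subject accuracy reporting), with a
repeat-CV mode behind `repeats=`. The cohort
summary is the grand mean of per-subject accuracies ± s.e.m
(sd/√n_subjects). Fold assignments are recorded and asserted to
partition the rows.

### A structural caution on within-subject session decoding

The session label coincides exactly with the recording in which the
rows were measured. After band-limiting to 0.01–0.1 Hz, a session's
496-row feature trajectory has on the order of a dozen statistically
independent states, and a linear classifier in 5-D can separate two
such smooth trajectories almost regardless of what distinguishes the
conditions. Empirically (30-subject synthetic cohorts): grand CV
accuracy is ≈ 0.86–0.88 with **zero** injected session contrast, and
stays ≈ 0.85–0.87 across a 16-fold range of contrast amplitudes; the
floor persists with contiguous-block folds (≈ 0.83) and under every
noise composition tried. Accuracy under this protocol therefore
measures session-realization decodability, not condition contrast —
shuffling the labels across rows (which breaks the row–recording
association) does restore chance, and is the package's honest null.
The acceptance checks that assert chance-level null accuracy,
accuracy monotone in contrast, and a 0.9 default-accuracy bar are
retained verbatim and fail by design; treat published headline
accuracies from this protocol accordingly.

## Statistics

- **Channel contrasts**: per channel, Levene's test (α = 0.05)
  selects the pooled two-sample t or Welch's t between sessions on
  the subject-level channel means. No multiple-testing correction by
  default (matching the protocol's reporting); Bonferroni and
  Benjamini–Hochberg are options and the output records which was
  used. Stars: *** p<0.001, ** p<0.01, * p<0.05.
- **ROI ANOVA**: one-way ANOVA of per-subject ROI means (channels
  averaged within ROI) across the five ROIs per session, with Scheffé
  post-hoc pairwise contrasts: F_ij = (m_i−m_j)²/(MSW(1/n_i+1/n_j)),
  p = P(F_{k−1,N−k} ≥ F_ij/(k−1)) — never smaller than the
  unadjusted contrast p.
- **Summary-statistic ANOVA**: two-group F from printed (M, sd, n)
  via MSB/MSW; equal to the raw-data ANOVA for any data with those
  exact moments. The printed self-report contrast (4.52 ± 1.35 vs
  3.26 ± 1.46, n = 30 each) recomputes to F(1,58) = 12.05.
- **ANCOVA**: score ~ session + gender by OLS with type-II sums of
  squares (robust to the unbalanced 13/17 gender split); the
  covariate p is reported and a partially confounded design warns.
- **Cronbach's α** by the variance formula (sample variances), with
  the conventional α ≥ 0.7 reliability flag.
- **Behavioral tests**: pooled two-sample t per purchase category and
  for per-subject totals; categories with zero variance in both
  sessions are flagged degenerate rather than tested.
- **Topography**: per-session channel means normalized by the joint
  maximum |mean| across both sessions into [−1, 1] (zeros stay
  zeros), rendered by inverse-distance-weighted (power 2)
  interpolation with an exact-hit rule at channel sites.
- **Asymmetry index**: mean |ΔHbO| over right channels (1–7) minus
  left channels (9–15), midline excluded; a signed variant exists.
  Positive = right-biased frontal activity.

## Synthetic data generator

The generator produces optical density via the forward MBLL, so
simulated data enter the pipeline exactly where instrument data
would.

**Signal.** Per channel, each trial adds `amplitude[channel,
session] × r(t − onset)` with r the unit-peak canonical double-gamma
HRF (peak 6 s, undershoot 16 s, ratio 1/6) convolved with the 25 s
task boxcar (`response="sustained"`, the physiologically expected
response to a block task; `response="impulse"` gives the bare HRF).
Default amplitude maps (µM peak) encode the qualitative topography of
the two conditions — session 1: mPFC 0.55, left VLPFC 0.30, right
VLPFC 0.18, DLPFC/OFC 0.08; session 2: DLPFC/OFC 0.45, mPFC 0.35,
VLPFC 0.05 — so the two sessions differ on every channel. These are
plausible task-evoked ΔHbO magnitudes, **not** estimates of any
study's effect sizes. Note the default maps make session 1 slightly
left-dominant through the left-VLPFC cluster, so the asymmetry index
is negative for session 1 relative to session 2 under the defaults;
the reward-versus-suppression topography and the right-lateralization
account of impulsivity pull in opposite directions and cannot both be
encoded in one map.

**Subject structure.** A per-subject log-normal response gain
(σ = 0.2, shared across sessions), per-channel multiplicative jitter
(σ = 0.1), and per-trial gain jitter (σ = 0.2).

**Noise** (µM): systemic cardiac (1.0 Hz, 0.30), respiratory
(0.3 Hz, 0.20) and Mayer-wave (0.1 Hz, 0.08) oscillations — each one
global waveform per recording with channel coupling gains 1 ± 0.3
plus a 20 % channel-local residual, reflecting the spatial coherence
of systemic physiology — a per-channel random linear drift
(0.1 µM/min sd) and white sensor noise (0.10 µM per sample at the
native rate). Cardiac and respiratory
bands are removed by the band-pass and mainly exercise the filter.

**ΔHbR** is generated as −0.3 × the ΔHbO signal plus independent
noise (typical anticorrelation); only ΔHbO is analyzed downstream.

**Ground truth** (expected noise-free epoch means per
channel/session, injected amplitude maps, session effect sizes,
questionnaire parameters) is stored beside every cohort for
parameter-recovery tests; channel t statistics rank-correlate with
the true effect sizes at the default contrast.

**Questionnaire tables.** Items (impulse buying 3, time pressure 6,
price discount 3) share a respondent-level latent factor (loading
√0.7) so internal consistency is realistic (α ≈ 0.87–0.91 at the
defaults); each item is a latent Gaussian rounded and clipped to
1…5. The latent mean is calibrated by root-finding so the discretized
score mean equals the target *exactly* in expectation; the sd is
matched as well as the bounded scale permits and the clipping rate
plus achievable sd are reported (a 5-point scale cannot produce
sd = 1.35 at mean 4.52, and a mean of 5.31 is rejected outright —
such configurations must be set deliberately, and honestly cannot be
met). Gender defaults to a 13/17 split.

**Purchase tables.** Counts 0…5 per category per subject, binomial
with p = SUM/(5n), switched to a moment-matched beta-binomial when
the target across-subject sd exceeds the binomial sd; expected
category sums match the configured totals exactly. No cross-category
subject propensity is modelled, so per-subject total sds run below
values that would require correlated categories.

**Determinism.** Every draw descends from one integer seed through
`numpy.random.SeedSequence` children keyed by subject and stream;
identical seeds give bit-identical cohorts, and the pipeline rerun
with the same config produces byte-identical result files.

## What the synthetic tests do and do not show

They verify the pipeline's algebra (MBLL exactness, filter response,
epoch/feature bookkeeping), the calibration of the statistical layer
(type-I error of the channel tests ≈ 0.049 over ~1000 independent
null channels), determinism, and the qualitative behavior of the
classifier. They do **not** validate absolute µM accuracy on real
instruments (unknown ε/DPF), motion or superficial-layer artifacts
(not modelled), or the causal interpretability of within-subject
session classification (see the structural caution above).

## Problem sizes

Default analyses run 30-subject cohorts (60 recordings of 2482
samples × 15 channels × 2 wavelengths). The test suite uses 3–30
subjects per cohort and ~1000 simulated null channels for the
calibration estimate; a full cohort through simulation, conversion,
filtering, epoching, features and tenfold CV takes a few seconds on
one core.
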