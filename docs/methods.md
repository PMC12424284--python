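# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `breathdyn`, and what the synthetic-data tests do
and do not establish about real recordings.

## Signal model and breath extraction

A belt recording is a single displacement channel sampled at `fs`
(default 10 Hz). Preprocessing is a zero-phase (forward–backward)
2nd-order Butterworth band-pass with cut-offs 0.05 and 3 Hz: the high-pass
removes baseline drift and the DC level, the low-pass removes sensor
noise above any plausible breathing harmonic. Zero phase matters because
the downstream quantities are extrema *timings*. After filtering, the
residual mean (edge transients) is subtracted so the zero-crossing
baseline is exactly 0; the recording must exceed three time constants of
the high-pass (> 60 s at 0.05 Hz) for the filter to be stable.

Extrema detection follows the zero-crossing rule: the maximum between an
upward and the next downward crossing is a peak, the minimum between a
downward and the next upward crossing a trough. Only crossing-bracketed
segments yield extrema, so partial first/last cycles are discarded by
construction. Two refinements make the rule robust to noise:

- **Ripple pruning.** Noise near the baseline creates spurious
  crossing pairs and hence spurious extrema. Adjacent peak/trough pairs
  whose vertical distance falls below `amp_min_frac` (default 0.3) times
  the median adjacent excursion are removed, smallest first, each
  removal deleting one peak and one trough so alternation is preserved
  and the split breath is merged back together. The cited zero-crossing
  literature prunes small excursions but fixes no constant; 0.3 is a
  configurable default.
- **Extremum timing refinement.** Breath tops are locally flat, so
  under noise the raw argmax wanders by several samples. When the
  estimated sample noise (robust second-difference estimate) exceeds 2%
  of the signal SD, each extremum index is re-estimated as the vertex of
  a least-squares parabola over ±0.15 breath periods, rounded back to
  the sample grid. On clean signals the raw argmax is already exact and
  refinement is skipped (it would otherwise inherit a small bias from
  asymmetric breath flanks).

Rates are assigned to the later peak of each interval, so the rate and
amplitude series share indices 2..n of the peak sequence. Amplitude uses
a ±2-sample local average at each extremum to suppress single-sample
noise. Recordings with fewer than 20 breaths are flagged and excluded
from the dynamics metrics.

## Dynamics metrics

All metrics treat the per-breath series as unit-sampled sequences
(breath index, not clock time): ACW lags are in breaths, PSD frequencies
in cycles/breath. No interpolation to clock time is performed — the
metrics are computed directly on the breath-indexed series.

- **mean, SD, CV** — SD uses the n−1 denominator; CV = SD/mean and is
  undefined (error) for zero-mean series.
- **ACW-50** — biased ACF (n denominator), computed by FFT; ACW-50 is
  the first *integer* lag below 0.5 (no interpolation). If the ACF never
  drops below 0.5 within the lag budget (n/2 by default) the value is
  capped there and flagged. Note the biased, demeaned ACF must cross 0.5
  within n/2 lags for any series, so the cap only binds with a
  user-restricted `max_lag`.
- **PSD slope** — periodogram of the mean-removed series over
  0 < f ≤ 0.5; OLS of log₁₀P on log₁₀f over all positive frequencies
  (no band restriction). The reported β is the *positive* power-law
  exponent (−slope), so a decrease in β reads as a shift toward faster
  frequencies; the raw regression slope is recorded alongside.
- **LZC** — binarization at the series mean with ties mapping to 1;
  LZ76 exhaustive parsing. Convention: each phrase is the shortest
  substring not contained in the prefix ending one character before the
  phrase's last; a trailing remainder still reproducible from the
  history closes the parse without a new phrase, so a constant series
  has c = 1. Normalization c·log₂(n)/n makes iid coin flips ≈ 1.
- **SampEn** — template matching with Chebyshev distance, m = 2,
  r = 0.2 × SD (n−1), delay 1, self-matches excluded; both the m- and
  (m+1)-level counts run over the n−m templates whose extension exists
  (Richman–Moorman convention). If either count is zero the value is an
  undefined NaN, not an arbitrary large number.
- **MSE** — coarse-graining by non-overlapping τ-block means, scales
  1..min(10, n/10); the tolerance r is fixed from the *original* series'
  SD at every scale (Costa's convention; per-scale recomputation is
  available as an option). The summary is the mean of the finite
  per-scale values. With fixed r, coarse-graining a white-dominated
  series lowers its per-scale entropy (variance shrinks under the fixed
  tolerance), while structured slow variance keeps it high — this is
  what makes MSE a complexity rather than an irregularity measure.

Rest and task recordings differ in length (≈5 vs ≈30 min), and entropy
estimators are length-biased. The default uses the full series; a
`match_length` option truncates the task series to the rest breath
count. The default mirrors common practice but conflates condition with
series length for SampEn/MSE/LZC — a documented caveat.

## Table transforms

Statistical inference runs on log-transformed features (natural log of
strictly positive columns; columns with any non-positive value —
typically the PSD slopes — pass through unchanged and are recorded).
Site harmonization is a location/scale adjustment per feature: each
site's values are standardized by site moments and rescaled to the
pooled moments. This is ComBat's location/scale core without
empirical-Bayes shrinkage, which needs more sites than the two-site
designs targeted here; after harmonization every site's feature mean
equals the grand mean exactly. Subject-condition rows with any missing
feature (undefined entropy, failed extraction) are excluded listwise and
logged.

## Inference

**PCA** operates on the feature correlation matrix (features have
heterogeneous units), retains eigenvalues > 1, applies Kaiser-normalized
varimax, orders rotated components by explained variance and sign-fixes
each so its largest-|loading| entry is positive. Communalities are
rotation-invariant and serve as an internal check. When all eigenvalues
hover near 1 (identity-correlation limit) retention is knife-edge and the
result carries an `unstable_retention` flag.

**Paired comparisons** use two-sided paired t-tests on diff = rest −
task (task increases give negative t, matching the reporting convention
of rest/task tables), BH step-up FDR across the 16 features, and paired
Cohen's d = mean(diff)/SD(diff), which equals t/√n — an identity the
acceptance suite exploits to validate effect sizes against published t
statistics without any raw data.

**PLSC.** Both blocks are z-scored (n−1), R = X′Y/(n−1) is the
cross-block correlation matrix, and R = USV′ its SVD. covexp_i =
s_i²/Σs_j² is the LV's share of cross-block covariance. Design choices
the literature leaves open, resolved here:

- *Permutation scheme*: rows of Y permuted uniformly; permuted singular
  values compared LV-by-LV without Procrustes rotation of the permuted
  decomposition (the simplest defensible reading); p = (1 + exceed)/(n_perm + 1).
- *Bootstrap*: subjects resampled jointly; each replicate's saliences
  aligned to the original via orthogonal Procrustes on U (same rotation
  applied to V) to prevent sign/axis flips; percentile 2.5/97.5 CIs;
  reliable ⇔ CI excludes 0. Degenerate resamples (constant column) are
  redrawn and counted.
- *Anxiety Y-block*: the 21 BAI items by default — a single-column Y
  admits only one latent variable, which cannot express multi-LV
  structure; the summed score is available via `y_block="total"`.
- *Efficiency*: accuracy / mean RT over correct trials (inverse-
  efficiency convention; all-responded-trials RT is an option), one
  column per N-back load, speeds pooled within load.

**A note on planted coupling strengths.** Because PLSC z-scores both
blocks, the singular values of the *population* cross-correlation matrix
— not the raw latent strengths — are what the estimator recovers. The
test suite therefore validates `gen_coupled_blocks` against an
analytically constructed population R rather than a strength-ratio rule
of thumb.

## Synthetic cohorts: what they emulate

The generator's defaults define the emulated study conditions, chosen
once to be physiologically plausible and not revisited:

- **Design**: 51 subjects with paired 5-min rest / 30-min task
  recordings at 10 Hz (a rest-only mode generates questionnaire-style
  cohorts, e.g. n = 210); two sites (belt gains 1.0/1.6, rate offsets
  0/+0.8 bpm) assigned alternately.
- **Rest** (14 bpm, amplitude 1.0 a.u.): the rate and log-amplitude
  series carry a slow sinusoidal modulation (≈15-breath period, jittered
  per subject; 1.4 bpm and 0.18 log-units) plus mild white jitter
  (0.30 bpm, 0.08 log-units) — a slowly modulated quasi-periodic rhythm
  with long timescales and low entropy at every coarse-graining scale.
- **Task** (17 bpm, amplitude 0.7 a.u.): near-white AR(1) series
  (φ = 0.2–0.3, marginal SDs 2.0 bpm / 0.25 log-units) — faster,
  shallower, more variable and more entropic breathing, with short
  timescales and a flatter spectrum.
- **Planted directions**: the twelve feature shifts implied by this
  contrast (mean rate ↑, mean amplitude ↓, rate SD ↑, amplitude CV ↑,
  both ACWs ↓, rate PSD slope ↓, both LZCs ↑, both MSEs ↑, rate
  SampEn ↑ under task) are recorded per cohort as ground truth; effect
  magnitudes are set large enough to be individually detectable at
  n = 51 under FDR, since directional recovery — not magnitude
  calibration — is what the closed loop tests.
- **Couplings**: a per-subject *entropy latent* scales the rest white
  jitter (log-multiplier 0.35/SD) and drives the Beck-anxiety latent
  (ρ = 0.6; items are 0–3 discretizations of a Gaussian item latent). A
  per-subject *variability latent* scales the task rate-AR innovation SD
  and lowers N-back accuracy (−0.5 logits/SD) while raising RT
  (+0.15 log-s/SD), so SD/CV of the task rate series anti-correlate with
  efficiency. The two latents are independent, keeping the variability
  and entropy channels separable.
- **Waveform**: raised-cosine arcs between extrema (troughs at 0, peaks
  at the planted amplitudes), so planted peak-to-peak intervals are
  exact up to sample quantization, plus white measurement noise
  (SD 0.05 a.u.).

What passing the closed loop shows: the pipeline recovers planted
breath timings (≲0.2 bpm mean rate error at realistic SNR), planted
timescales/spectra/entropy orderings, planted condition shifts and
planted cross-block couplings from raw waveforms. What it does not
show: robustness to apnea, sighs, movement artifacts, missing belt
contact, non-stationary site drift, or breathing-phase effects — real
recordings contain all of these and the generator deliberately models
none of them.

## Numerical conventions and degenerate inputs

Seeds thread through `numpy.random.SeedSequence`; every stochastic
operation takes an explicit seed and cohort generation is a
deterministic function of (spec, seed). Constant series are errors for
CV/ACW/PSD/SampEn and a defined c = 1 for LZC. SampEn's undefined case
(no matches) propagates as NaN into the feature table and is handled by
the listwise missing-data policy. Varimax iterates to a 1e-10 relative
criterion (500 iterations max). BH adjustment delegates to statsmodels'
step-up implementation and is tested against the literal definition.

## Problem sizes in the validation suite

The acceptance checks use: brute-force SampEn agreement up to n = 200;
exhaustive LZ76 agreement on all binary strings to length 12; AR(1)
timescale recovery at n = 10⁵; spectral-exponent recovery at n = 4096;
PLSC null calibration with 500 replicates × 200 permutations at
n = 100, p = 16, q = 3; and 100 full synthetic cohorts (n = 51) for
end-to-end sign and salience recovery, with 30 cohorts in the faster
reproduction script.
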