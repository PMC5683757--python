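# Methods

This note documents the models, estimators and numerical choices behind
`betaevents`, and what the synthetic-data tests do and do not establish about
real recordings.

## Spectral analysis

Each trial's prestimulus window (default [−1000, 0] ms relative to stimulus
onset) is convolved with complex Morlet wavelets

    w(t, f0) = A exp(−t² / 2σt²) exp(2πi f0 t),   σt = m / (2π f0),
    A = 1 / (σt √(2π)),

with a constant number of cycles m = 7, and power is the squared magnitude of
the convolution. The frequency grid is 1–60 Hz in 1 Hz steps for 600 Hz
human-style data (1–100 Hz is appropriate for 1 kHz rodent LFP); the integer
grid keeps the inclusive 15–29 Hz beta band exactly 15 rows wide. Convolution
runs over the full window with zero padding ("same" output); wavelets longer
than the window (below ~7 Hz at 1 s) are flagged in provenance, and all
time-resolved statistics are reported on the edge-trimmed interval
[−900, −100] ms. The wavelet is evaluated on a ±5σt grid, which truncates
less than 1e−5 of its mass; the FFT-based convolution matches a direct
summation oracle to 1e−10 relative tolerance.

Power is normalized per frequency to factors of median (FOM): each row is
divided by the median of its raw power over all trials and time points of one
dataset (ordinary midpoint median). Normalization is per subject/session and
never pools datasets. FOM normalization is scale-invariant and idempotent.

## Event definitions

A beta event is a regional maximum of the full-frequency FOM spectrogram
whose peak frequency falls in the band and whose power strictly exceeds the
cutoff (default 6× median). Regional maxima use standard image-morphology
semantics: a connected (8-neighborhood) plateau of equal values none of whose
pixels has a strictly greater neighbor; a plateau yields one event at its
grid-rounded centroid (snapped to the nearest plateau pixel for concave
plateaus — on continuous-valued spectrograms plateaus are singletons and the
rule is vacuous). Maxima are found before band-filtering so band-edge
cropping cannot create artificial peaks.

Event duration and frequency span are full widths at half maximum along the
fixed-frequency row and fixed-time column through the peak. Crossings are
located by linear interpolation between the bracketing samples; when a window
boundary is reached before the power falls below half maximum, the width is
twice the uncut half-width and an edge flag is set; a peak cut on both sides
of an axis raises an error rather than fabricating a width. Note a
resolution property used in the tests: a burst whose *amplitude* envelope is
Gaussian with FWHM F, analyzed with a wavelet of amplitude FWHM w, produces a
*power* bump of FWHM √(F² + w²)/√2 — at 20 Hz and m = 7 the wavelet
contributes w ≈ 131 ms, so 150 ms bursts measure ≈ 141 ms wide. Peak
frequency estimates carry a small (+1–2 Hz) upward bias for short bursts
because the wavelet's spectral acceptance widens with frequency at constant
m; this is a property of the estimator, not a defect of the implementation.

"Non-overlapping events" are maximal contiguous runs of time points at which
any band frequency exceeds the cutoff. Each region carries its band-power
peak, FWHM features about that peak, and the number of ordinary maxima it
contains. Region counts are *not* monotone in the cutoff (a region can split
in two as the cutoff rises); the monotone property is nesting — every
higher-cutoff region lies inside exactly one lower-cutoff region — and that
is what the tests assert.

Per-trial summaries are the event count, the means of power/duration/span
over the trial's events, and the most-recent-event timing (largest peak time,
≤ 0). Event-conditional features are undefined on zero-event trials and those
trials are excluded from any statistic using them.

## Behavior statistics

Detect/attend probability (DP/AP) is the trapezoidal AUROC of a trial feature
against the binary outcome, oriented so DP < 0.5 means higher values predict
the negative outcome; ties get half credit (Mann–Whitney convention).
Per-dataset 95% CIs use a percentile bootstrap (default 1000 resamples) over
trials, unstratified; resamples that lose a class are redrawn. A dataset is
individually significant when the CI's upper bound is below 0.5. Across
datasets the one-sample left-tailed Wilcoxon signed-rank test against 0.5
uses the exact null distribution for n ≤ 25 without ties (so the one-tailed
floor 1/2¹⁰ = 9.77×10⁻⁴ at n = 10 is reproduced exactly) and drops zero
differences.

Pooled-average comparisons pair condition means by dataset and use a
right-tailed paired t-test (negative condition entered first); effect sizes
are Cohen's d with the (n₁+n₂−2)-denominator pooled SD. Percent-change-from-
mean (PCM) curves sort trials by feature (seeded shuffle among ties), slide a
21-trial boxcar over the positive-outcome indicator, normalize to
100·(rate−mean)/mean and resample to 100 points by linear interpolation
before averaging datasets. Feature–power correlations are per-dataset Pearson
r against trial mean band power, compared across features by a Friedman test
with Holm–Bonferroni-corrected one-tailed signed-rank post-hocs. The optimal
event-number criterion maximizes TPR − FPR for the rule "predict the negative
outcome when count ≥ criterion", ties to the smallest criterion.

Histogram matching trims trials at random (seeded, without replacement)
within key bins — integer event counts, or 20 ms bins of most-recent-event
timing starting at −1000 ms — so both conditions have identical per-bin
counts; only ≥1-event trials participate. Matching a key removes its
condition difference *exactly*, which is why the dissociation tests assert
equality of matched means rather than a large p-value.

## Temporal statistics

Event-occurrence probability histograms use 50 ms windows sliding in 1 ms
steps, per condition and dataset, with pointwise across-dataset left-tailed
signed-rank tests (no multiplicity correction; these curves are exploratory,
as the shading they feed is). IEIs are consecutive peak-time differences in
trials with ≥ 2 events, pooled per dataset; default histogram bins are 15 ms
(20 ms for condition and jitter comparisons). FF = Var/mean of per-trial
counts and CV² = Var/mean² of IEIs use the unbiased (n−1) variance; both
equal 1 for a Poisson process.

Intervals longer than the window are unobservable, which biases the raw
pooled CV² of a Poisson train well below 1 (the observed-interval density is
f(x) ∝ (T−x)λe^(−λx) on (0, T): CV² ≈ 0.62 at 1.2 events/s, ≈ 0.77 at
3 events/s in a 1 s window; verified by simulation). `cv2_window_corrected`
divides the raw estimate by the analytic censored value at the rate
estimated from the mean count, restoring ≈ 1 for Poisson input; the
calibration checks report this corrected estimator.

The jitter null for non-overlapping events re-places each trial's regions
uniformly at random, preserving region count, durations and within-trial
order, by splitting the free space with a flat Dirichlet over gaps — this is
exactly the uniform distribution over feasible arrangements and needs no
rejection sampling. Peaks keep their offset within the region; 1000 passes
are averaged.

## Generator-mechanism discrimination

Trials are band-pass filtered at 15–29 Hz with a 150 ms Hamming-window FIR
applied forward–backward (zero phase, so peak times are not lag-shifted) and
Hilbert-transformed. The characteristic beta period is the inverse of the
median instantaneous frequency (phase derivative via central differences)
over all interior samples of a dataset. The amplitude cutoff is 2× the
dataset-median envelope; the supra-cutoff time fraction is reported so users
can check the ≈10% correspondence with the 6× spectral cutoff.

Oscillation peaks are 0°-phase time points — upward crossings of the
unwrapped phase through integer multiples of 2π, located by linear
interpolation (sub-sample precision matters at 600 Hz, ~12 samples per beta
cycle). Above-cutoff lags connect the first and last peak within each
supra-cutoff region; below-cutoff lags connect the last peak of a region to
the first peak of the *next* region of the same trial (only consecutive
pairs). Lags are divided by the period, rounded to integer cycle counts for
matching, and mapped to the normalized modulo ((lag/period + 0.5) mod 1) −
0.5 ∈ [−0.5, 0.5], where 0 means an integer number of periods. The two
cycle-count histograms are equalized by seeded random down-sampling without
replacement before uniformity is assessed on each side by a χ² test over 20
equal bins and by the circular resultant length R = |mean exp(2πi·modulo)|.
A flat below-cutoff distribution (χ² not rejected) classifies the dataset as
bursty; concentration at 0 as amplitude modulation of a sustained rhythm.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
the biophysics of beta generation:

- **Background**: 1/f^n noise (default n = 1) by spectral shaping of white
  Gaussian noise with seeded phases, zero mean and unit sample variance per
  trial; 600 Hz sampling, 1 s prestimulus windows.
- **Bursty**: Gaussian-windowed sinusoids whose amplitude-envelope FWHM is
  the burst duration (default 150 ms), peak frequency drawn uniformly in
  18–22 Hz (where the beta power-spectral bump concentrates; a full 15–29 Hz
  draw is available but smears the period-modulo statistics), amplitude 5×
  the noise scale by default, and an independent random phase per burst, so
  rhythmicity exists only inside bursts. Trials split evenly between
  conditions; per-trial counts are Poisson at the condition rate (defaults
  1.0 vs 2.5 events/s), centers uniform with ≥ 1 FWHM center-to-center
  spacing (Dirichlet-gap construction, i.e. uniform conditioned on the
  spacing). Infeasibly large counts are redrawn up to 100 times — a soft
  truncation that biases the realized rate by < 0.3% at 2.5 events/s — and a
  placement error naming the trial is raised when the rate is genuinely
  infeasible. An optional timing bias shifts the last event of negative
  trials toward the stimulus. Ground truth records every injection.
- **Amplitude-modulated**: one continuous sinusoid per trial (default
  21 Hz, random initial phase) times a strictly positive log-normal envelope
  (median 1, log-SD 0.55, smoothing scale 80 ms), phase-continuous through
  low-amplitude epochs by construction. The log-normal tail gives ≈ 10% of
  time points above the 2×-median amplitude cutoff, matching the regime the
  discrimination analysis expects; an additive Gaussian envelope cannot be
  both strictly positive and that heavy-tailed.

Independent child streams (noise, events, labels, envelope) derive from one
seed, so identical (spec, seed) pairs are bit-reproducible and a zero burst
rate reproduces the background realization exactly.

What passing tests show — and don't: the fixtures have stationary 1/f
backgrounds, homogeneous burst amplitudes and exactly Poisson counts. Real
recordings add line noise, artifacts, non-stationary arousal effects,
heterogeneous event amplitudes (which make the cutoff-correlation curve peak
at intermediate cutoffs rather than saturate) and unknown label-coupling
mechanisms. Recovery and discrimination results here validate the
*estimators*, not any claim about a particular dataset.

## Problem sizes and defaults

Calibration and recovery checks run at: 10,000 trials for the Poisson Fano
factor, 5,000 for CV², 10 datasets × 200 trials for null-DP and for the
rate/timing coupling analyses, 5 × 300 trials for the rate-recovery grid, and
20 replicates × 200 trials per generator for the discrimination contrast —
sizes chosen so Monte-Carlo error is several times smaller than each check's
tolerance. Analysis defaults (6× FOM cutoff, m = 7, 15–29 Hz, 21-trial PCM
boxcar, 1000 bootstrap/jitter passes, 2× amplitude factor, 50 ms/1 ms
histogram windows, 20 ms matching bins, 15 ms IEI bins) are the published
constants of the analysis this package implements and are carried in
`RunConfig`.

## Known limitations

- Single channel per dataset; no source modeling or cross-channel matching.
- FWHM frequency spans are computed on the 1 Hz grid; spans below ~2 Hz are
  grid-limited.
- The jitter null assumes regions are exchangeable in position; it does not
  model slow within-trial rate trends.
- The below-cutoff lag set mixes gap lengths; at high burst rates short gaps
  retain residual phase correlation through the band-pass filter, so
  discrimination fixtures use moderate rates (≤ 1.5 events/s).
- Exact signed-rank p-values are used only for n ≤ 25 without ties; beyond
  that the normal approximation applies.
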