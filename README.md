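# betaevents

Transient beta-event analysis for trial-epoched neural time series.

In sensorimotor cortex, beta-band (15–29 Hz) activity does not ride along as a
sustained oscillation: on single trials it appears as brief (~150 ms)
high-power events, and the *rate* and *timing* of those events in the second
before a stimulus predict whether the stimulus will be detected or attended.
`betaevents` implements that analysis chain for anyone working with
trial-epoched single-channel MEG/EEG/LFP data and binary behavioral outcomes:

- **Spectral events.** Per-trial time-frequency representations (TFR) from
  complex Morlet wavelets, `w(t, f0) = A exp(−t²/2σt²) exp(2πi f0 t)` with
  `σt = m/(2π f0)`, constant `m = 7` cycles and `A = 1/(σt√(2π))`; power
  normalized per frequency to factors of median (FOM) over all prestimulus
  samples of a dataset. Beta events are regional maxima of the FOM
  spectrogram with peak frequency in band and power above a cutoff (default
  6× median), with full-width-at-half-maximum duration and frequency span.
  An alternative "non-overlapping event" definition treats each contiguous
  supra-cutoff temporal region as one event.
- **Behavior statistics.** Detect/attend probability `DP = AUROC(feature,
  outcome)` with bootstrap confidence intervals (DP < 0.5: higher feature
  values predict the *negative* outcome), exact one-sample Wilcoxon
  signed-rank tests across datasets, Cohen's d, sliding percent-change-from-
  mean rate curves, Friedman + Holm–Bonferroni feature comparisons, optimal
  event-count criteria, and histogram-matched trial trimming that dissociates
  event number from event timing.
- **Temporal statistics.** Sliding event-occurrence histograms, inter-event
  intervals (IEI), Fano factor `FF = Var[N]/E[N]` and `CV² = Var[IEI]/E[IEI]²`
  (both 1 for a Poisson process; a window-censoring correction is provided),
  and an order-preserving jitter null for non-overlapping events.
- **Generator mechanism test.** Band-pass + Hilbert phase analysis that asks
  whether rhythmicity survives low-amplitude epochs: time lags between
  oscillation peaks, taken modulo the characteristic beta period and
  normalized to [−0.5, 0.5], are compared above vs below a 2×-median
  amplitude cutoff. A sustained amplitude-modulated rhythm concentrates both
  lag sets at 0; a bursty generator concentrates only the above-cutoff set.
- **Synthetic data.** Seeded generators for 1/f^n background, bursty epochs
  (Gaussian-windowed sinusoids with per-condition Poisson rates and optional
  timing bias, with ground truth) and amplitude-modulated epochs, so the
  whole pipeline is testable without recordings.

## Worked example

```python
import numpy as np
import betaevents as be

spec = be.GeneratorSpec(kind="bursty", n_trials=200, seed=42,
                        burst_rate=(1.0, 2.5))       # events/s per condition
epochs, truth = be.gen_bursty_epochs(spec)

fom = be.fom_normalize(be.morlet_tfr(epochs, np.arange(1.0, 61.0), m=7))
events = be.detect_events(fom, band=(15, 29), cutoff=6.0)
summaries = be.summarize_trials(events, epochs.n_trials)

counts = np.array([s.n_events for s in summaries], float)
pos = epochs.positive_mask
fv = be.FeatureVector(epochs.dataset_id, "event_number", counts, pos)
res = be.detect_probability(fv, n_boot=1000, seed=0)
```

Output for this seed:

```
events detected: 373
mean rate  detected trials: 1.05 /s
mean rate  non-detected trials: 2.68 /s
mean event duration: 195 ms
event-number DP: 0.210  (95% CI 0.152-0.271)
Fano factor of event counts: 1.49
```

The detected per-condition rates recover the injected 1.0 vs 2.5 events/s
(detected durations are broadened relative to the injected 150 ms envelope by
the wavelet's own temporal width). The detect probability of 0.21 — far below
0.5, with the bootstrap CI excluding 0.5 — says higher event counts predict
the non-detected condition, and the Fano factor above 1 reflects the
between-condition rate difference inflating count variance.

The same steps are available from the shell:

```bash
betaevents synth --kind bursty --rate-pos 1.0 --rate-neg 2.5 \
    --n-trials 200 --seed 42 --out demo/
betaevents events --epochs demo/epochs.h5 --out demo/events.tsv
betaevents run --epochs demo/epochs.h5 --seed 0 --out demo/results/
```

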