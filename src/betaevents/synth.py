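"""Synthetic trial-epoched data with the statistical structure the analysis
assumes, plus ground truth.

Three generator kinds:

``background_only``
    1/f^n noise, synthesized by spectral shaping of white Gaussian noise
    (exactly seedable; exponent 0 is white noise).

``bursty``
    Transient beta bursts — Gaussian-windowed sinusoids whose amplitude
    envelope has a controlled FWHM (~150 ms) — added to 1/f background.
    Trials are split evenly between a positive (detected / attend-in) and a
    negative condition; per-trial event counts are Poisson at the
    condition-specific rate, event centers uniform in the window subject to a
    non-overlap spacing, and an optional timing bias shifts the last event of
    negative-condition trials toward the stimulus. Each burst gets an
    independent random initial phase, so rhythmicity exists only inside
    bursts (the bursty-generator mechanism).

``amplitude_modulated``
    A single continuous sinusoid per trial (fixed random initial phase)
    multiplied by a slowly varying strictly positive envelope, plus
    background. Phase is continuous through low-amplitude epochs by
    construction (the dynamic-amplitude-modulation mechanism).

All generators honor a determinism contract: identical (spec, seed) pairs
reproduce identical output bit for bit. Independent child streams are used
for noise, event placement and labels, so e.g. a zero burst rate yields
exactly the background realization of the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import EpochSet

POSITIVE = "detected"
NEGATIVE = "nondetected"

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = this * sigma


class InvalidSpecError(ValueError):
    """Raised when a generator spec is inconsistent or infeasible."""


class PlacementError(RuntimeError):
    """Raised when non-overlapping burst placement fails for a trial."""


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic dataset.

    ``burst_rate`` is (positive-condition, negative-condition) expected events
    per 1 s trial. ``burst_freq`` is the (low, high) range the per-event peak
    frequency is drawn from; the default 18-22 Hz matches where the beta
    power-spectral bump concentrates. ``burst_duration_ms`` is the FWHM of the
    burst's amplitude envelope. ``timing_bias_ms`` shifts the last event of
    each negative-condition trial toward the stimulus. ``envelope_process``
    configures the amplitude-modulated generator's envelope
    (``kind``: ``slow_gaussian`` | ``ornstein_like``, ``mean``, ``std``,
    ``tau_ms`` smoothing/correlation scale).
    """

    kind: str = "bursty"
    n_trials: int = 200
    fs: float = 600.0
    window: tuple = (-1000.0, 0.0)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    burst_rate: tuple = (1.0, 2.5)
    burst_freq: tuple = (18.0, 22.0)
    burst_duration_ms: float = 150.0
    burst_amplitude: float = 5.0
    timing_bias_ms: float = 0.0
    carrier_freq: float = 21.0
    envelope_process: dict = field(default_factory=lambda: {
        "kind": "slow_gaussian", "median": 1.0, "std": 0.55, "tau_ms": 80.0,
    })
    seed: int = 0

    def validate(self):
        if self.kind not in ("bursty", "amplitude_modulated", "background_only"):
            raise InvalidSpecError(f"unknown generator kind {self.kind!r}")
        if self.fs <= 0:
            raise InvalidSpecError("fs must be positive")
        if self.window[1] <= self.window[0]:
            raise InvalidSpecError("empty window")
        if self.noise_exponent < 0:
            raise InvalidSpecError("noise_exponent must be >= 0")
        if any(r < 0 for r in self.burst_rate):
            raise InvalidSpecError("burst_rate entries must be >= 0")
        fmax = max(self.burst_freq[1], self.carrier_freq)
        if self.fs <= 2 * fmax:
            raise InvalidSpecError("fs must exceed twice the highest frequency")

    @property
    def n_samples(self) -> int:
        return int(round((self.window[1] - self.window[0]) / 1000.0 * self.fs))

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs * 1000.0


@dataclass
class InjectedEvent:
    center_ms: float
    freq_hz: float
    fwhm_ms: float
    amplitude: float


@dataclass
class GroundTruth:
    """Injected-event record for every trial, plus labels and the spec echo."""

    events: list            # list (per trial) of lists of InjectedEvent
    labels: np.ndarray      # str per trial
    kind: str
    spec: GeneratorSpec

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trial, evs in enumerate(self.events):
            for e in evs:
                rows.append({
                    "trial": trial, "center_ms": e.center_ms,
                    "freq_hz": e.freq_hz, "fwhm_ms": e.fwhm_ms,
                    "amplitude": e.amplitude, "label": self.labels[trial],
                })
        return pd.DataFrame(rows, columns=["trial", "center_ms", "freq_hz",
                                           "fwhm_ms", "amplitude", "label"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _streams(seed: int, n: int = 4):
    """Independent child generators (noise, events, labels, envelope)."""
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# background noise
# ---------------------------------------------------------------------------


def _noise(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """1/f^n noise via spectral shaping of white noise; zero mean per trial."""
    n = spec.n_samples
    white = rng.standard_normal((spec.n_trials, n))
    if spec.noise_exponent == 0:
        out = white * spec.noise_scale
    else:
        spectrum = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n, d=1.0 / spec.fs)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-spec.noise_exponent / 2.0)
        spectrum *= shape
        out = np.fft.irfft(spectrum, n=n, axis=1)
        # keep unit sample variance regardless of exponent, then scale
        out /= out.std(axis=1, keepdims=True)
        out *= spec.noise_scale
    return out - out.mean(axis=1, keepdims=True)


def gen_background(spec: GeneratorSpec) -> EpochSet:
    """Pure 1/f^n background noise epochs."""
    spec.validate()
    if spec.kind != "background_only":
        raise InvalidSpecError("gen_background requires kind='background_only'")
    rng_noise, _, rng_labels, _ = _streams(spec.seed)
    data = _noise(spec, rng_noise)
    labels = _balanced_labels(spec.n_trials, rng_labels)
    return EpochSet(data=data, fs=spec.fs, t0=spec.window[0], t1=spec.window[1],
                    labels=labels, positive_label=POSITIVE,
                    dataset_id=f"synth-bg-{spec.seed}",
                    attrs={"generator": asdict(spec)})


def _balanced_labels(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.array([POSITIVE, NEGATIVE])[
        np.arange(n_trials) % 2
    ].astype(object)
    return rng.permutation(labels).astype(str)


# ---------------------------------------------------------------------------
# event-time sampling
# ---------------------------------------------------------------------------


def _place_spaced(n: int, lo: float, hi: float, spacing: float,
                  rng: np.random.Generator) -> np.ndarray:
    """n ordered points uniform in [lo, hi] with consecutive gaps >= spacing.

    Sequential-gap construction: the free space left after reserving the
    minimum gaps is split by a flat Dirichlet, which is exactly the
    distribution of i.i.d. uniform points conditioned on the spacing.
    """
    span = hi - lo
    free = span - (n - 1) * spacing
    if free < 0:
        raise PlacementError("spacing infeasible")
    gaps = rng.dirichlet(np.ones(n + 1)) * free
    return lo + np.cumsum(gaps[:-1]) + spacing * np.arange(n)


def gen_event_times(rate_per_s: float, n_trials: int, window=(-1000.0, 0.0),
                    dispersion: str = "poisson", theta: float = 1.0,
                    jitter_ms: float = 0.0, seed: int = 0):
    """Point-process event-time samples (no waveforms), per trial.

    ``dispersion``:

    - ``poisson``: counts Poisson(rate x T), times i.i.d. uniform.
    - ``negative_binomial``: counts NB with mean rate x T and shape ``theta``
      (variance mean + mean^2 / theta), times uniform.
    - ``regular``: evenly spaced at 1/rate with a random global phase and
      i.i.d. Gaussian jitter of SD ``jitter_ms``.
    """
    if rate_per_s < 0:
        raise InvalidSpecError("rate must be >= 0")
    if dispersion not in ("poisson", "negative_binomial", "regular"):
        raise InvalidSpecError(f"unknown dispersion {dispersion!r}")
    rng = np.random.default_rng(seed)
    t0, t1 = window
    T = (t1 - t0) / 1000.0
    mean = rate_per_s * T
    out = []
    for _ in range(n_trials):
        if dispersion == "regular":
            if rate_per_s == 0:
                out.append(np.empty(0))
                continue
            period = 1000.0 / rate_per_s
            phase = rng.uniform(0, period)
            times = np.arange(t0 + phase, t1, period)
            times = times + rng.standard_normal(len(times)) * jitter_ms
            out.append(np.sort(times[(times >= t0) & (times < t1)]))
            continue
        if dispersion == "poisson":
            n = rng.poisson(mean)
        else:
            # NB as gamma-mixed Poisson
            n = rng.poisson(rng.gamma(theta, mean / theta)) if mean > 0 else 0
        out.append(np.sort(rng.uniform(t0, t1, n)))
    return out


# ---------------------------------------------------------------------------
# bursty generator
# ---------------------------------------------------------------------------


def _burst_waveform(times_ms, center, freq, fwhm, amplitude, phase):
    sigma = fwhm / _GAUSS_FWHM  # amplitude-envelope sigma, ms
    t = times_ms - center
    return amplitude * np.exp(-(t**2) / (2 * sigma**2)) * np.cos(
        2 * np.pi * freq * t / 1000.0 + phase
    )


def gen_bursty_epochs(spec: GeneratorSpec, max_count_retries: int = 100):
    """Bursty-generator epochs plus ground truth.

    Per trial: the condition label fixes the Poisson rate; burst centers are
    uniform in the window (inset half a FWHM) with center-to-center spacing of
    at least one burst FWHM, so injected peaks stay resolvable and ground
    truth unambiguous; each burst is a Gaussian-windowed sinusoid with an
    independent random phase. In negative-condition trials the last burst is shifted
    ``timing_bias_ms`` toward the stimulus (clipped to stay feasible). Counts
    whose spacing is infeasible in the window are redrawn up to
    ``max_count_retries`` times before a :class:`PlacementError` names the
    trial.
    """
    spec.validate()
    if spec.kind != "bursty":
        raise InvalidSpecError("gen_bursty_epochs requires kind='bursty'")
    rng_noise, rng_events, rng_labels, _ = _streams(spec.seed)
    data = _noise(spec, rng_noise)
    labels = _balanced_labels(spec.n_trials, rng_labels)
    times = spec.times
    t0, t1 = spec.window
    dur = spec.burst_duration_ms
    lo, hi = t0 + dur / 2.0, t1 - dur / 2.0
    spacing = dur  # one FWHM of margin between burst centers
    rate = dict(zip((POSITIVE, NEGATIVE), spec.burst_rate))
    mean_T = (t1 - t0) / 1000.0

    truth_events = []
    for trial in range(spec.n_trials):
        lam = rate[labels[trial]] * mean_T
        centers = None
        for _ in range(max_count_retries):
            n = rng_events.poisson(lam)
            if n == 0:
                centers = np.empty(0)
                break
            if (n - 1) * spacing <= hi - lo:
                centers = _place_spaced(n, lo, hi, spacing, rng_events)
                break
        if centers is None:
            raise PlacementError(
                f"trial {trial}: cannot place a feasible burst count at rate "
                f"{rate[labels[trial]]}/s with spacing {spacing} ms"
            )
        if (len(centers) and labels[trial] == NEGATIVE
                and spec.timing_bias_ms > 0):
            shifted = centers[-1] + spec.timing_bias_ms
            floor = centers[-2] + spacing if len(centers) > 1 else lo
            centers[-1] = np.clip(shifted, floor, hi)
        evs = []
        for c in centers:
            f = rng_events.uniform(*spec.burst_freq)
            phase = rng_events.uniform(0, 2 * np.pi)
            amp = spec.burst_amplitude * spec.noise_scale
            data[trial] += _burst_waveform(times, c, f, dur, amp, phase)
            evs.append(InjectedEvent(float(c), float(f), float(dur), float(amp)))
        truth_events.append(evs)

    epochs = EpochSet(data=data, fs=spec.fs, t0=t0, t1=t1, labels=labels,
                      positive_label=POSITIVE,
                      dataset_id=f"synth-bursty-{spec.seed}",
                      attrs={"generator": asdict(spec)})
    return epochs, GroundTruth(truth_events, labels, "bursty", spec)


# ---------------------------------------------------------------------------
# amplitude-modulated generator
# ---------------------------------------------------------------------------


def _envelope(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying strictly positive envelope, one row per trial.

    Both kinds exponentiate a unit-variance slow Gaussian process g, giving a
    log-normal envelope ``median * exp(std * g)`` (heavy upper tail, as
    empirical neural amplitude envelopes show). ``slow_gaussian`` builds g by
    Gaussian-kernel smoothing of white noise (kernel SD ``tau_ms``);
    ``ornstein_like`` uses a stationary AR(1) with correlation time
    ``tau_ms``. A non-positive ``median`` would make the envelope negative or
    zero everywhere and raises an invalid-spec error.
    """
    from scipy.signal import fftconvolve as _fftconv

    p = spec.envelope_process
    kind = p.get("kind", "slow_gaussian")
    median = float(p.get("median", 1.0))
    std = float(p.get("std", 0.55))
    tau = float(p.get("tau_ms", 80.0))
    if median <= 0:
        raise InvalidSpecError(
            "envelope median must be positive (envelope would not be "
            "strictly positive)"
        )
    n = spec.n_samples
    if kind == "slow_gaussian":
        sigma_samp = tau / 1000.0 * spec.fs
        half = int(np.ceil(4 * sigma_samp))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma_samp) ** 2)
        k /= np.linalg.norm(k)  # unit-variance output for white input
        raw = rng.standard_normal((spec.n_trials, n + 2 * half))
        g = _fftconv(raw, k[np.newaxis, :], mode="valid", axes=1)
    elif kind == "ornstein_like":
        a = np.exp(-1000.0 / (tau * spec.fs))
        e = rng.standard_normal((spec.n_trials, n))
        g = np.empty_like(e)
        g[:, 0] = e[:, 0]
        c = np.sqrt(1 - a * a)
        for i in range(1, n):
            g[:, i] = a * g[:, i - 1] + c * e[:, i]
    else:
        raise InvalidSpecError(f"unknown envelope kind {kind!r}")
    return median * np.exp(std * g)


def gen_modulated_epochs(spec: GeneratorSpec):
    """Amplitude-modulated (sustained-rhythm) epochs plus ground truth.

    One continuous sinusoid at ``carrier_freq`` per trial, with a fixed random
    initial phase, multiplied by a strictly positive slowly varying envelope;
    background noise added. Phase is continuous across high- and low-envelope
    epochs by construction. Ground truth records no discrete events.
    """
    spec.validate()
    if spec.kind != "amplitude_modulated":
        raise InvalidSpecError(
            "gen_modulated_epochs requires kind='amplitude_modulated'")
    rng_noise, rng_events, rng_labels, rng_env = _streams(spec.seed)
    data = _noise(spec, rng_noise)
    labels = _balanced_labels(spec.n_trials, rng_labels)
    env = _envelope(spec, rng_env)
    t = spec.times / 1000.0
    phases = rng_events.uniform(0, 2 * np.pi, spec.n_trials)
    carrier = np.cos(2 * np.pi * spec.carrier_freq * t[np.newaxis, :]
                     + phases[:, np.newaxis])
    amp = spec.burst_amplitude * spec.noise_scale
    data = data + amp * env * carrier
    epochs = EpochSet(data=data, fs=spec.fs, t0=spec.window[0],
                      t1=spec.window[1], labels=labels,
                      positive_label=POSITIVE,
                      dataset_id=f"synth-am-{spec.seed}",
                      attrs={"generator": asdict(spec)})
    truth = GroundTruth([[] for _ in range(spec.n_trials)], labels,
                        "amplitude_modulated", spec)
    return epochs, truth


def generate(spec: GeneratorSpec):
    """Dispatch on ``spec.kind``; returns (EpochSet, GroundTruth or None)."""
    if spec.kind == "background_only":
        return gen_background(spec), None
    if spec.kind == "bursty":
        return gen_bursty_epochs(spec)
    return gen_modulated_epochs(spec)
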