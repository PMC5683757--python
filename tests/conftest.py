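import numpy as np
import pytest

import betaevents as be

FREQS = np.arange(1.0, 61.0)
BAND = (15.0, 29.0)
CUTOFF = 6.0


@pytest.fixture(scope="session")
def bursty_dataset():
    """One moderate bursty dataset with rate coupling, analyzed end to end."""
    spec = be.GeneratorSpec(kind="bursty", n_trials=80, seed=11,
                            burst_rate=(1.0, 2.5))
    epochs, truth = be.gen_bursty_epochs(spec)
    fom = be.fom_normalize(be.morlet_tfr(epochs, FREQS))
    events = be.detect_events(fom, BAND, CUTOFF)
    summaries = be.summarize_trials(events, epochs.n_trials)
    return {
        "spec": spec, "epochs": epochs, "truth": truth, "tfr": fom,
        "events": events, "summaries": summaries,
    }


@pytest.fixture(scope="session")
def small_fom_tfr():
    """A tiny FOM TFR (noise only) for oracle comparisons."""
    spec = be.GeneratorSpec(kind="background_only", n_trials=5, seed=3)
    epochs = be.gen_background(spec)
    return be.fom_normalize(be.morlet_tfr(epochs, FREQS))


def make_tfr(power, freqs=None, times=None, fs=600.0, units="FOM"):
    """Hand-constructed TFRSet for synthetic spectrogram tests."""
    power = np.asarray(power, dtype=float)
    n_f, n_t = power.shape[1], power.shape[2]
    if freqs is None:
        freqs = np.arange(1.0, n_f + 1.0)
    if times is None:
        times = -1000.0 + np.arange(n_t) / fs * 1000.0
    return be.TFRSet(power=power, freqs=np.asarray(freqs, float),
                     times=np.asarray(times, float), units=units, fs=fs,
                     m_cycles=7.0)


def gaussian_bump(freqs, times, f0, t0, sigma_f, sigma_t, peak):
    """Separable Gaussian bump on a (freqs x times) grid."""
    F = np.exp(-((freqs - f0) ** 2) / (2 * sigma_f**2))[:, None]
    T = np.exp(-((times - t0) ** 2) / (2 * sigma_t**2))[None, :]
    return peak * F * T
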