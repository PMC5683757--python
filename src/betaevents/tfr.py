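"""Morlet time-frequency analysis and factor-of-median normalization.

Per-trial spectrograms are computed by convolving each trial with a complex
Morlet wavelet

    w(t, f0) = A exp(-t^2 / (2 sigma_t^2)) exp(2 i pi f0 t),

with sigma_t = m / (2 pi f0), amplitude A = 1 / (sigma_t sqrt(2 pi)) and a
constant number of cycles m (default 7). Power is the squared magnitude of
the convolution. Power is normalized per frequency to factors of median
(FOM): each frequency row is divided by the median of its raw power over all
trials and prestimulus time points of one dataset. Normalization is per
subject/session dataset; never pool across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.stats import pearsonr

from .io import DEFAULT_BAND, DEFAULT_TRIM, DEFAULT_WINDOW, EpochSet

#: default power-cutoff grid for the cutoff variation analysis:
#: 0.25, 0.5, then integers 1..16 (18 points)
DEFAULT_CUTOFF_GRID = (0.25, 0.5) + tuple(float(c) for c in range(1, 17))


class UnitsError(ValueError):
    """Raised when an operation receives a TFR in the wrong units."""


class DegenerateInputError(ValueError):
    """Raised on degenerate inputs (e.g. a zero median at some frequency)."""


@dataclass
class TFRSet:
    """Trials x frequencies x times power array with axis vectors.

    ``units`` is ``"raw"`` or ``"FOM"``; ``freq_median`` holds the
    per-frequency raw-power median used for normalization (present iff
    units == "FOM").
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    units: str
    fs: float
    m_cycles: float
    freq_median: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    def band_indices(self, band) -> np.ndarray:
        lo, hi = band
        return np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))

    def time_indices(self, window) -> np.ndarray:
        lo, hi = window
        return np.flatnonzero((self.times >= lo) & (self.times <= hi))


def morlet_wavelet(f0: float, fs: float, m: float) -> np.ndarray:
    """Complex Morlet wavelet sampled on a +/- 5 sigma_t grid (truncation
    carries < 1e-5 of the mass)."""
    sigma_t = m / (2.0 * np.pi * f0)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    amp = 1.0 / (sigma_t * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f0 * t)


def morlet_tfr(epochs: EpochSet, freqs, m: float = 7.0) -> TFRSet:
    """Morlet spectrogram of every trial, in raw power units.

    Convolution uses the full window with implicit zero padding ("same"
    output). If the window is shorter than one wavelet at the lowest
    frequency, an edge-effect warning is recorded in provenance (not an
    error); time-resolved statistics should be read on the trimmed interval.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or len(freqs) == 0:
        raise ValueError("freqs must be a non-empty 1-D vector")
    if np.any(freqs <= 0) or np.any(freqs >= epochs.fs / 2.0):
        raise ValueError("freqs must lie in (0, fs/2)")
    if m < 1:
        raise ValueError("m must be >= 1")

    n_trials, n_samples = epochs.data.shape
    power = np.empty((n_trials, len(freqs), n_samples))
    provenance = {"m_cycles": m, "edge_warnings": []}
    for j, f0 in enumerate(freqs):
        w = morlet_wavelet(f0, epochs.fs, m)
        if len(w) > n_samples:
            provenance["edge_warnings"].append(
                f"wavelet at {f0:g} Hz ({len(w)} samples) longer than the "
                f"window ({n_samples} samples); edges dominated by padding"
            )
        conv = fftconvolve(epochs.data, w[np.newaxis, :], mode="same", axes=1)
        power[:, j, :] = np.abs(conv) ** 2
    return TFRSet(
        power=power,
        freqs=freqs,
        times=epochs.times.copy(),
        units="raw",
        fs=epochs.fs,
        m_cycles=m,
        provenance=provenance,
    )


def fom_normalize(tfr: TFRSet) -> TFRSet:
    """Normalize a raw TFR to factors of median (FOM) per frequency.

    The median at each frequency is taken over all trials and all time points
    of this dataset (midpoint convention for even counts, i.e. the ordinary
    sample median). Idempotent up to scale: normalizing an already-normalized
    TFR returns it unchanged because each row's median is 1.
    """
    if tfr.n_trials < 2:
        raise ValueError("FOM normalization needs >= 2 trials")
    med = np.median(tfr.power, axis=(0, 2))
    zero = np.flatnonzero(med == 0)
    if len(zero):
        raise DegenerateInputError(
            f"zero median power at frequencies {tfr.freqs[zero]} Hz"
        )
    out = tfr.power / med[np.newaxis, :, np.newaxis]
    return TFRSet(
        power=out,
        freqs=tfr.freqs.copy(),
        times=tfr.times.copy(),
        units="FOM",
        fs=tfr.fs,
        m_cycles=tfr.m_cycles,
        freq_median=med if tfr.units == "raw" else tfr.freq_median,
        provenance=dict(tfr.provenance),
    )


def band_mean_power(tfr: TFRSet, band=DEFAULT_BAND, window=DEFAULT_WINDOW,
                    trim=DEFAULT_TRIM):
    """Trial mean power in a band, plus the edge-trimmed band time series.

    Returns ``(scalar, (trim_times, series))`` where ``scalar`` is the
    per-trial mean over the full band x window (the paper-style trial mean
    prestimulus power) and ``series`` is the per-trial band-mean at each time
    point, restricted to the trimmed interval (default [-900, -100] ms) to
    avoid wavelet edge effects.
    """
    bi = tfr.band_indices(band)
    ti = tfr.time_indices(window)
    if len(bi) == 0 or len(ti) == 0:
        raise ValueError("empty band/window intersection with the TFR axes")
    scalar = tfr.power[:, bi][:, :, ti].mean(axis=(1, 2))
    si = tfr.time_indices(trim)
    series = tfr.power[:, bi][:, :, si].mean(axis=1)
    return scalar, (tfr.times[si], series)


def percent_area_above(tfr: TFRSet, band=DEFAULT_BAND, window=DEFAULT_WINDOW,
                       cutoff: float = 6.0) -> np.ndarray:
    """Percent of band x window spectrogram pixels with power above cutoff,
    per trial."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    bi = tfr.band_indices(band)
    ti = tfr.time_indices(window)
    if len(bi) == 0 or len(ti) == 0:
        raise ValueError("empty band/window intersection with the TFR axes")
    block = tfr.power[:, bi][:, :, ti]
    return 100.0 * (block > cutoff).mean(axis=(1, 2))


def cutoff_correlation_scan(tfrs, band=DEFAULT_BAND, window=DEFAULT_WINDOW,
                            cutoffs=DEFAULT_CUTOFF_GRID):
    """Pearson r between percent-area-above-cutoff and trial mean band power,
    per cutoff and per dataset.

    ``tfrs`` is one TFRSet or a list of them (one per dataset). Returns
    ``(cutoffs, r_matrix, mean_r)`` with ``r_matrix`` of shape
    (n_datasets, n_cutoffs); r is NaN where the percent-area has zero
    variance.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any(cutoffs <= 0) or np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be positive and ascending")
    if isinstance(tfrs, TFRSet):
        tfrs = [tfrs]
    rows = []
    for tfr in tfrs:
        if tfr.n_trials < 3:
            raise ValueError("cutoff scan needs >= 3 trials")
        power, _ = band_mean_power(tfr, band, window)
        row = np.empty(len(cutoffs))
        for k, c in enumerate(cutoffs):
            area = percent_area_above(tfr, band, window, c)
            if np.ptp(area) == 0 or np.ptp(power) == 0:
                row[k] = np.nan
            else:
                row[k] = pearsonr(area, power).statistic
        rows.append(row)
    r = np.vstack(rows)
    valid = (~np.isnan(r)).sum(axis=0)
    mean_r = np.full(r.shape[1], np.nan)
    has = valid > 0
    mean_r[has] = np.nansum(r[:, has], axis=0) / valid[has]
    return cutoffs, r, mean_r
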