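"""Beta-event detection and per-event / per-trial feature computation.

A beta event is a regional maximum of a trial's FOM-normalized spectrogram
whose peak frequency lies in the beta band and whose peak power exceeds a
cutoff (default 6x median). Regional maxima are connected components
(8-connectivity) of pixels with no strictly greater neighbor; a plateau
component yields one event at its grid-rounded centroid. Maxima are searched
on the full-frequency TFR and then filtered to band peaks, so band-edge
cropping cannot manufacture spurious maxima.

Event duration and frequency span are full widths at half maximum measured
along the fixed-frequency row and fixed-time column through the peak, with
half-maximum crossings located by linear interpolation. When a window edge is
reached before the power falls below half maximum, the width is twice the
uncut half-width and the corresponding edge flag is set.

The alternative "non-overlapping event" definition treats each maximal
contiguous supra-cutoff temporal region of the band spectrogram as one event,
carrying the count of ordinary maxima it contains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import DEFAULT_BAND, DEFAULT_WINDOW
from .tfr import TFRSet, UnitsError


class DegenerateWidthError(ValueError):
    """Peak sits on both boundaries of an axis; no half-width is measurable."""


class ConsistencyError(ValueError):
    """Event table refers to trials outside the epoch set."""


@dataclass
class SpectralEvent:
    """One detected beta event (original, local-maximum definition)."""

    trial: int
    peak_time: float      # ms
    peak_freq: float      # Hz
    peak_power: float     # FOM
    duration: float       # ms, FWHM along time
    fspan: float          # Hz, FWHM along frequency
    time_edge: bool = False
    freq_edge: bool = False


@dataclass
class TrialEventSummary:
    """Per-trial event count and feature means (None when no events)."""

    trial: int
    n_events: int
    mean_power: float | None
    mean_duration: float | None
    mean_fspan: float | None
    most_recent_timing: float | None


@dataclass
class NonOverlappingEvent:
    """One maximal contiguous supra-cutoff temporal region."""

    trial: int
    onset: float          # ms, first supra-cutoff sample
    offset: float         # ms, exclusive end of the last supra-cutoff sample
    peak_time: float
    peak_freq: float
    peak_power: float
    n_maxima: int
    duration: float
    fspan: float
    time_edge: bool = False
    freq_edge: bool = False


# ---------------------------------------------------------------------------
# regional maxima
# ---------------------------------------------------------------------------

_STRUCT8 = np.ones((3, 3), dtype=bool)


def regional_maxima(matrix: np.ndarray):
    """Regional maxima of a 2-D array under 8-connectivity.

    A regional maximum is a connected plateau of equal-valued pixels none of
    which has a strictly greater 8-neighbor (the standard regional-maxima
    semantics of image-morphology toolboxes). Each plateau yields one
    ``(row, col, value)`` triple at its grid-rounded centroid (snapped to the
    nearest plateau pixel when the centroid of a concave plateau falls
    outside it).
    """
    matrix = np.asarray(matrix, dtype=float)
    greater = ndimage.maximum_filter(matrix, size=3, mode="constant",
                                     cval=-np.inf)
    mask = matrix >= greater  # no strictly greater neighbor
    # a plateau partly outside `mask` has a greater neighbor somewhere, so
    # the whole plateau is disqualified: flag mask pixels with an
    # equal-valued neighbor outside the mask and drop their components
    bad = np.zeros_like(mask)
    nr, nc = matrix.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            src = (slice(max(dr, 0), nr + min(dr, 0)),
                   slice(max(dc, 0), nc + min(dc, 0)))
            dst = (slice(max(-dr, 0), nr + min(-dr, 0)),
                   slice(max(-dc, 0), nc + min(-dc, 0)))
            bad[dst] |= (matrix[src] == matrix[dst]) & ~mask[src]
    bad &= mask
    labeled, n = ndimage.label(mask, structure=_STRUCT8)
    drop = set(np.unique(labeled[bad])) - {0}
    out = []
    objects = ndimage.find_objects(labeled)
    for lab in range(1, n + 1):
        if lab in drop:
            continue
        sl = objects[lab - 1]
        rr, cc = np.nonzero(labeled[sl] == lab)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        r = int(np.round(rr.mean()))
        c = int(np.round(cc.mean()))
        if labeled[r, c] != lab:
            # centroid of a concave plateau fell off the component: snap to
            # the nearest component pixel
            k = np.argmin((rr - r) ** 2 + (cc - c) ** 2)
            r, c = int(rr[k]), int(cc[k])
        out.append((r, c, float(matrix[rr[0], cc[0]])))
    return out


# ---------------------------------------------------------------------------
# FWHM
# ---------------------------------------------------------------------------


def _fwhm_1d(values: np.ndarray, axis_vals: np.ndarray, peak_idx: int):
    """FWHM of a 1-D profile around ``peak_idx``.

    Walks outward to the first crossings of half the peak value, locating each
    crossing by linear interpolation between the bracketing samples. Returns
    ``(width, edge_flag)``; if one boundary is reached before crossing, the
    width is twice the uncut half-width and the flag is set. Raises
    :class:`DegenerateWidthError` when both sides are cut.
    """
    half = values[peak_idx] / 2.0
    peak_pos = axis_vals[peak_idx]

    def walk(step):
        i = peak_idx
        while True:
            j = i + step
            if j < 0 or j >= len(values):
                return None  # cut by the boundary
            if values[j] < half:
                # linear interpolation between samples i and j
                frac = (values[i] - half) / (values[i] - values[j])
                return abs((axis_vals[i] + frac * (axis_vals[j] - axis_vals[i]))
                           - peak_pos)
            i = j

    left = walk(-1)
    right = walk(+1)
    if left is None and right is None:
        raise DegenerateWidthError(
            "power never falls below half maximum on either side of the peak"
        )
    if left is None:
        return 2.0 * right, True
    if right is None:
        return 2.0 * left, True
    return left + right, False


def compute_fwhm(tfr: TFRSet, trial: int, freq_idx: int, time_idx: int):
    """FWHM duration (ms) and frequency span (Hz) of a detected maximum.

    Returns ``(duration, fspan, time_edge, freq_edge)``.
    """
    plane = tfr.power[trial]
    duration, time_edge = _fwhm_1d(plane[freq_idx, :], tfr.times, time_idx)
    fspan, freq_edge = _fwhm_1d(plane[:, time_idx], tfr.freqs, freq_idx)
    return duration, fspan, time_edge, freq_edge


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_events(tfr: TFRSet, band=DEFAULT_BAND, cutoff: float = 6.0):
    """Detect beta events in every trial of a FOM spectrogram.

    One event per regional maximum of the full-frequency TFR whose peak
    frequency lies in ``band`` (inclusive) and whose power strictly exceeds
    ``cutoff``. Events are sorted by (trial, peak_time).
    """
    if tfr.units != "FOM":
        raise UnitsError("detect_events requires a FOM-normalized TFR")
    lo, hi = band
    if lo < tfr.freqs.min() or hi > tfr.freqs.max():
        raise ValueError("band outside the TFR frequency axis")
    out = []
    for trial in range(tfr.n_trials):
        for fi, ti, value in regional_maxima(tfr.power[trial]):
            f = tfr.freqs[fi]
            if not (lo <= f <= hi) or not (value > cutoff):
                continue
            duration, fspan, t_edge, f_edge = compute_fwhm(tfr, trial, fi, ti)
            out.append(SpectralEvent(
                trial=trial,
                peak_time=float(tfr.times[ti]),
                peak_freq=float(f),
                peak_power=value,
                duration=duration,
                fspan=fspan,
                time_edge=t_edge,
                freq_edge=f_edge,
            ))
    out.sort(key=lambda e: (e.trial, e.peak_time))
    return out


def summarize_trials(events, n_trials: int, window=DEFAULT_WINDOW):
    """Per-trial event count, feature means and most-recent-event timing.

    Feature means are ``None`` for zero-event trials. The most recent event is
    the one whose peak time is largest (closest to stimulus onset; prestimulus
    times are <= 0).
    """
    by_trial = [[] for _ in range(n_trials)]
    for e in events:
        if e.trial < 0 or e.trial >= n_trials:
            raise ConsistencyError(f"event trial {e.trial} >= n_trials {n_trials}")
        by_trial[e.trial].append(e)
    out = []
    for trial, evs in enumerate(by_trial):
        if not evs:
            out.append(TrialEventSummary(trial, 0, None, None, None, None))
            continue
        out.append(TrialEventSummary(
            trial=trial,
            n_events=len(evs),
            mean_power=float(np.mean([e.peak_power for e in evs])),
            mean_duration=float(np.mean([e.duration for e in evs])),
            mean_fspan=float(np.mean([e.fspan for e in evs])),
            most_recent_timing=float(max(e.peak_time for e in evs)),
        ))
    return out


def detect_nonoverlapping(tfr: TFRSet, band=DEFAULT_BAND, cutoff: float = 6.0):
    """Detect non-overlapping beta events (contiguous supra-cutoff regions).

    A time point is supra-cutoff when any band frequency exceeds the cutoff
    there; maximal runs of such points form regions. Each region carries the
    band-power maximum inside it (peak), FWHM features about that peak, and
    the number of ordinary (local-maximum) events whose peak time falls in it.
    """
    if tfr.units != "FOM":
        raise UnitsError("detect_nonoverlapping requires a FOM-normalized TFR")
    bi = tfr.band_indices(band)
    maxima = detect_events(tfr, band, cutoff)
    dt = 1000.0 / tfr.fs
    out = []
    for trial in range(tfr.n_trials):
        block = tfr.power[trial][bi, :]
        supra = (block > cutoff).any(axis=0)
        if not supra.any():
            continue
        # maximal runs of supra-cutoff time points
        edges = np.flatnonzero(np.diff(np.concatenate(([0], supra.view(np.int8),
                                                       [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            sub = block[:, start:stop]
            fi_rel, ti_rel = np.unravel_index(np.argmax(sub), sub.shape)
            fi = bi[fi_rel]
            ti = start + ti_rel
            duration, fspan, t_edge, f_edge = compute_fwhm(tfr, trial, fi, ti)
            onset = float(tfr.times[start])
            offset = float(tfr.times[stop - 1] + dt)
            n_max = sum(1 for e in maxima
                        if e.trial == trial and onset <= e.peak_time < offset)
            out.append(NonOverlappingEvent(
                trial=trial, onset=onset, offset=offset,
                peak_time=float(tfr.times[ti]), peak_freq=float(tfr.freqs[fi]),
                peak_power=float(tfr.power[trial, fi, ti]),
                n_maxima=max(n_max, 1),
                duration=duration, fspan=fspan,
                time_edge=t_edge, freq_edge=f_edge,
            ))
    out.sort(key=lambda e: (e.trial, e.onset))
    return out


def maxima_power_survival(tfr: TFRSet, band=DEFAULT_BAND, grid=None):
    """Survival function (1 - CDF) of all band local-maxima powers.

    No cutoff is applied: every regional maximum whose peak frequency lies in
    the band contributes. Returns ``(grid, survival)``.
    """
    if tfr.units != "FOM":
        raise UnitsError("maxima_power_survival requires a FOM-normalized TFR")
    lo, hi = band
    powers = []
    for trial in range(tfr.n_trials):
        for fi, ti, value in regional_maxima(tfr.power[trial]):
            if lo <= tfr.freqs[fi] <= hi:
                powers.append(value)
    if not powers:
        raise ValueError("no band maxima found")
    powers = np.sort(powers)
    if grid is None:
        grid = np.linspace(0.0, powers[-1], 200)
    grid = np.asarray(grid, dtype=float)
    survival = 1.0 - np.searchsorted(powers, grid, side="right") / len(powers)
    return grid, survival


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def events_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "trial": e.trial, "peak_time_ms": e.peak_time,
            "peak_freq_hz": e.peak_freq, "peak_power_fom": e.peak_power,
            "duration_ms": e.duration, "fspan_hz": e.fspan,
            "time_edge": e.time_edge, "freq_edge": e.freq_edge,
        } for e in events],
        columns=["trial", "peak_time_ms", "peak_freq_hz", "peak_power_fom",
                 "duration_ms", "fspan_hz", "time_edge", "freq_edge"],
    )


def nonoverlapping_frame(regions) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "trial": e.trial, "onset_ms": e.onset, "offset_ms": e.offset,
            "n_maxima": e.n_maxima, "peak_time_ms": e.peak_time,
            "peak_freq_hz": e.peak_freq, "peak_power_fom": e.peak_power,
            "duration_ms": e.duration, "fspan_hz": e.fspan,
            "time_edge": e.time_edge, "freq_edge": e.freq_edge,
        } for e in regions],
        columns=["trial", "onset_ms", "offset_ms", "n_maxima", "peak_time_ms",
                 "peak_freq_hz", "peak_power_fom", "duration_ms", "fspan_hz",
                 "time_edge", "freq_edge"],
    )


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "trial": s.trial, "n_events": s.n_events,
            "mean_power_fom": s.mean_power, "mean_duration_ms": s.mean_duration,
            "mean_fspan_hz": s.mean_fspan,
            "most_recent_timing_ms": s.most_recent_timing,
        } for s in summaries],
        columns=["trial", "n_events", "mean_power_fom", "mean_duration_ms",
                 "mean_fspan_hz", "most_recent_timing_ms"],
    )
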