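"""Time-resolved event statistics: occurrence histograms, inter-event
intervals, Fano factor, CV-squared and the constrained jitter null.

All event times are peak times in ms relative to stimulus onset, negative in
the prestimulus window. The occurrence histogram uses 50 ms windows sliding
in 1 ms steps and is reported on the edge-trimmed interval [-900, -100] ms;
the pointwise across-dataset signed-rank tests are exploratory and carry no
multiplicity correction.

The Fano factor (variance/mean of per-trial event counts) and CV^2
(variance/mean^2 of pooled inter-event intervals) both equal 1 for a Poisson
process. Intervals longer than the analysis window are unobservable, which
biases the raw pooled CV^2 of a Poisson train below 1;
:func:`cv2_window_corrected` removes that bias by dividing by the analytic
CV^2 of the window-censored Poisson interval distribution
f(x) proportional to (T - x) exp(-lambda x) at the estimated rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .io import DEFAULT_TRIM, DEFAULT_WINDOW


class InfeasibleJitterError(ValueError):
    """Regions cannot be re-placed inside the window."""


@dataclass
class EventTimeSeriesStats:
    times: np.ndarray        # window-center grid, ms
    prob_pos: np.ndarray     # mean occurrence probability, positive condition
    prob_neg: np.ndarray
    sem_pos: np.ndarray
    sem_neg: np.ndarray
    p: np.ndarray            # pointwise signed-rank p (neg > pos)


def event_times_by_trial(events, n_trials: int):
    """Sorted peak-time arrays per trial from a SpectralEvent list."""
    out = [[] for _ in range(n_trials)]
    for e in events:
        out[e.trial].append(e.peak_time)
    return [np.sort(np.asarray(t)) for t in out]


def most_recent_by_trial(times_by_trial):
    """Singleton arrays holding each trial's latest event time (empty when
    the trial has no events)."""
    return [t[-1:] for t in times_by_trial]


def _occurrence_curve(times_by_trial, mask, starts, win_ms):
    """P(>= 1 event in [s, s+win)) per window start, over trials in mask."""
    rows = np.flatnonzero(mask)
    if len(rows) == 0:
        return np.full(len(starts), np.nan)
    hit = np.zeros(len(starts))
    for i in rows:
        t = times_by_trial[i]
        if len(t) == 0:
            continue
        # window s catches an event at t when s <= t < s + win
        inside = np.zeros(len(starts), dtype=bool)
        for ev in t:
            inside |= (starts <= ev) & (ev < starts + win_ms)
        hit += inside
    return hit / len(rows)


def event_time_histogram(times_by_dataset, positive_by_dataset,
                         window=DEFAULT_WINDOW, trim=DEFAULT_TRIM,
                         win_ms: float = 50.0, step_ms: float = 1.0,
                         min_datasets: int = 5) -> EventTimeSeriesStats:
    """Sliding-window event occurrence probability per condition.

    ``times_by_dataset``: list over datasets of per-trial event-time lists
    (use :func:`most_recent_by_trial` for the most-recent-event variant).
    Pointwise left-tailed Wilcoxon signed-rank across datasets tests whether
    occurrence is more probable in the negative condition. Curves and tests
    are reported on the trimmed interval.
    """
    if len(times_by_dataset) < min_datasets:
        raise ValueError(f"need >= {min_datasets} datasets for the pointwise test")
    starts = np.arange(window[0], window[1] - win_ms + step_ms / 2, step_ms)
    centers = starts + win_ms / 2.0
    keep = (centers >= trim[0]) & (centers <= trim[1])

    pos_curves, neg_curves = [], []
    for times, positive in zip(times_by_dataset, positive_by_dataset):
        positive = np.asarray(positive, dtype=bool)
        pos_curves.append(_occurrence_curve(times, positive, starts, win_ms))
        neg_curves.append(_occurrence_curve(times, ~positive, starts, win_ms))
    pos = np.vstack(pos_curves)[:, keep]
    neg = np.vstack(neg_curves)[:, keep]

    n = pos.shape[0]
    p = np.ones(pos.shape[1])
    for j in range(pos.shape[1]):
        diff = pos[:, j] - neg[:, j]
        nz = diff[diff != 0]
        if len(nz) == 0:
            p[j] = 1.0
        else:
            p[j] = stats.wilcoxon(nz, alternative="less").pvalue
    sem = lambda m: m.std(axis=0, ddof=1) / np.sqrt(n)  # noqa: E731
    return EventTimeSeriesStats(
        times=centers[keep],
        prob_pos=pos.mean(axis=0), prob_neg=neg.mean(axis=0),
        sem_pos=sem(pos), sem_neg=sem(neg), p=p,
    )


def histogram_frame(h: EventTimeSeriesStats) -> pd.DataFrame:
    return pd.DataFrame({
        "time_ms": h.times,
        "prob_pos": h.prob_pos, "prob_neg": h.prob_neg,
        "sem_pos": h.sem_pos, "sem_neg": h.sem_neg, "p": h.p,
    })


# ---------------------------------------------------------------------------
# burstiness
# ---------------------------------------------------------------------------


def inter_event_intervals(times_by_trial):
    """Pooled consecutive differences (ms) from trials with >= 2 events.

    Intervals longer than the analysis window are unobservable (censoring
    note in the module docstring).
    """
    ieis = [np.diff(t) for t in times_by_trial if len(t) >= 2]
    return np.concatenate(ieis) if ieis else np.empty(0)


def fano_factor(counts) -> float:
    """Variance/mean of per-trial event counts (unbiased variance)."""
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2:
        raise ValueError("Fano factor needs >= 2 trials")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("zero mean count: Fano factor undefined")
    return float(counts.var(ddof=1) / mean)


def cv2(ieis) -> float:
    """Variance/mean^2 of inter-event intervals (unbiased variance)."""
    ieis = np.asarray(ieis, dtype=float)
    if len(ieis) < 2:
        raise ValueError("CV^2 needs >= 2 intervals")
    mean = ieis.mean()
    if mean == 0:
        raise ValueError("zero mean interval: CV^2 undefined")
    return float(ieis.var(ddof=1) / mean**2)


def censored_poisson_cv2(rate_per_s: float, window_ms: float = 1000.0) -> float:
    """Analytic CV^2 of Poisson inter-event intervals observed inside a
    finite window.

    An interval of length x fits in the window with probability proportional
    to (T - x), so observed intervals follow
    f(x) ∝ (T - x) λ exp(-λ x) on (0, T); this returns Var/mean^2 under f.
    """
    lam = rate_per_s / 1000.0  # per ms
    T = window_ms

    def mom(k):
        return integrate.quad(
            lambda x: x**k * (T - x) * np.exp(-lam * x), 0.0, T)[0]

    z = mom(0)
    m1 = mom(1) / z
    m2 = mom(2) / z
    return (m2 - m1**2) / m1**2


def cv2_window_corrected(ieis, counts, window_ms: float = 1000.0) -> float:
    """Window-censoring-corrected CV^2 estimate.

    Estimates the event rate from the mean per-trial count, computes the raw
    pooled CV^2, and divides by the analytic censored-Poisson CV^2 at that
    rate, so a Poisson train yields ~1 regardless of the window.
    """
    counts = np.asarray(counts, dtype=float)
    rate = counts.mean() / (window_ms / 1000.0)
    return cv2(ieis) / censored_poisson_cv2(rate, window_ms)


# ---------------------------------------------------------------------------
# jitter null for non-overlapping events
# ---------------------------------------------------------------------------


def _jitter_trial(onsets, offsets, peaks, window, rng):
    """Re-place a trial's regions uniformly at random, preserving durations,
    order and disjointness (sequential-gap construction: free space divided
    by a flat Dirichlet, which is the uniform distribution over feasible
    arrangements)."""
    durations = offsets - onsets
    free = (window[1] - window[0]) - durations.sum()
    if free < 0:
        raise InfeasibleJitterError(
            "total region extent exceeds the window; cannot jitter")
    n = len(durations)
    gaps = rng.dirichlet(np.ones(n + 1)) * free
    new_onsets = window[0] + np.cumsum(gaps[:-1]) + np.concatenate(
        ([0.0], np.cumsum(durations[:-1])))
    return new_onsets + (peaks - onsets)


def jitter_null_iei(regions, n_trials: int, window=DEFAULT_WINDOW,
                    n_jitter: int = 1000, seed: int = 0, bin_ms: float = 20.0):
    """Jittered IEI null distribution for non-overlapping events.

    Each pass independently re-places every trial's supra-cutoff regions
    uniformly at random subject to (i) staying disjoint and (ii) preserving
    their within-trial order; peak times keep their offset inside the region.
    IEIs (successive peak-time differences) are pooled per pass; the returned
    null histogram is the average over passes.

    Returns ``(bin_edges, observed_hist, null_hist)`` as probability
    histograms over (0, window length].
    """
    rng = np.random.default_rng(seed)
    by_trial = [[] for _ in range(n_trials)]
    for r in regions:
        by_trial[r.trial].append(r)
    trials = []
    for regs in by_trial:
        if not regs:
            continue
        regs = sorted(regs, key=lambda r: r.onset)
        trials.append((
            np.array([r.onset for r in regs]),
            np.array([r.offset for r in regs]),
            np.array([r.peak_time for r in regs]),
        ))

    length = window[1] - window[0]
    edges = np.arange(0.0, length + bin_ms / 2, bin_ms)

    def hist(ieis):
        if len(ieis) == 0:
            return np.zeros(len(edges) - 1)
        h, _ = np.histogram(ieis, bins=edges)
        return h / len(ieis)

    observed = hist(np.concatenate(
        [np.diff(p) for _, _, p in trials] or [np.empty(0)]))
    null = np.zeros(len(edges) - 1)
    for _ in range(n_jitter):
        ieis = []
        for onsets, offsets, peaks in trials:
            new_peaks = _jitter_trial(onsets, offsets, peaks, window, rng)
            if len(new_peaks) >= 2:
                ieis.append(np.diff(new_peaks))
        null += hist(np.concatenate(ieis) if ieis else np.empty(0))
    null /= n_jitter
    return edges, observed, null
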