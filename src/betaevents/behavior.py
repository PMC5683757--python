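"""Statistics linking trial features to binary behavior.

Detect probability (DP) / attend probability (AP) is the area under the ROC
curve relating a trial feature to the behavioral outcome, oriented so that
DP < 0.5 means higher feature values predict the negative class
(non-detected / attend-out); 0.5 is no predictability. Ties receive half
credit (trapezoidal AUROC = Mann-Whitney U statistic). Per-dataset 95%
confidence intervals come from a percentile bootstrap over trials; a dataset
is flagged significant when the upper bound falls below 0.5. Across datasets,
a one-sample left-tailed Wilcoxon signed-rank test asks whether the median DP
is below 0.5 (exact null distribution for small n, so the one-tailed floor of
1/2^n, e.g. 9.77e-4 at n = 10, is reproduced exactly).

Event-conditional features (mean event power/duration/span, most-recent-event
timing) are defined only on trials with at least one event; those trials'
values are NaN in the feature vector and excluded before any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined (single class, zero variance...)."""


@dataclass
class FeatureVector:
    """One feature across the trials of one dataset, aligned with labels.

    ``values`` may contain NaN for trials where the feature is undefined
    (event-conditional features on zero-event trials). ``labels`` is boolean,
    True = positive class (detected / attend-in).
    """

    dataset_id: str
    name: str
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.values) != len(self.labels):
            raise ValueError("values and labels must have the same length")

    def defined(self):
        """(values, labels) with NaN trials dropped."""
        mask = ~np.isnan(self.values)
        return self.values[mask], self.labels[mask]


@dataclass
class DPResult:
    dp: float
    ci_low: float
    ci_high: float
    n_boot: int
    n: int

    @property
    def significant_below_half(self) -> bool:
        return self.ci_high < 0.5


def feature_vectors(summaries, band_power, positive_mask, dataset_id="dataset"):
    """Build the standard feature vectors from trial summaries + mean power.

    Returns a dict of FeatureVector keyed by feature name: ``mean_power``
    (trial mean prestimulus band power, defined on all trials),
    ``event_number`` (all trials) and the event-conditional features
    ``event_power``, ``event_duration``, ``event_fspan``,
    ``most_recent_timing``.
    """
    labels = np.asarray(positive_mask, dtype=bool)
    n = len(summaries)

    def col(getter):
        return np.array([np.nan if getter(s) is None else getter(s)
                         for s in summaries], dtype=float)

    out = {
        "mean_power": FeatureVector(dataset_id, "mean_power",
                                    np.asarray(band_power, float), labels),
        "event_number": FeatureVector(
            dataset_id, "event_number",
            np.array([s.n_events for s in summaries], float), labels),
        "event_power": FeatureVector(dataset_id, "event_power",
                                     col(lambda s: s.mean_power), labels),
        "event_duration": FeatureVector(dataset_id, "event_duration",
                                        col(lambda s: s.mean_duration), labels),
        "event_fspan": FeatureVector(dataset_id, "event_fspan",
                                     col(lambda s: s.mean_fspan), labels),
        "most_recent_timing": FeatureVector(
            dataset_id, "most_recent_timing",
            col(lambda s: s.most_recent_timing), labels),
    }
    for fv in out.values():
        if len(fv.values) != n:
            raise ValueError("summary/feature length mismatch")
    return out


def auroc(values, labels) -> float:
    """Trapezoidal AUROC of feature vs positive class, ties at half credit."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise UndefinedStatisticError("both classes required for ROC")
    return float(roc_auc_score(labels, values))


def detect_probability(fv: FeatureVector, n_boot: int = 1000,
                       seed: int = 0) -> DPResult:
    """DP/AP of one feature with a percentile bootstrap CI.

    Trials with undefined feature values are excluded first. The bootstrap
    resamples trials (unstratified) with replacement; resamples that lose one
    class are redrawn implicitly by being skipped.
    """
    values, labels = fv.defined()
    if len(values) == 0 or labels.all() or not labels.any():
        raise UndefinedStatisticError(
            f"{fv.name}: both classes required to compute DP")
    dp = auroc(values, labels)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = len(values)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
        boot[b] = auroc(values[idx], lab)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return DPResult(dp=dp, ci_low=float(lo), ci_high=float(hi),
                    n_boot=n_boot, n=n)


def group_dp_test(dp_values, null: float = 0.5, significant=None):
    """Across-dataset DP test: median, left-tailed signed-rank p vs ``null``,
    and the fraction of datasets individually significant.

    Zero differences are dropped (standard signed-rank convention); the exact
    null distribution is used for n <= 25 without ties, the normal
    approximation otherwise. If every value equals the null the test is
    degenerate and p = 1.0 is returned.
    """
    dp_values = np.asarray(dp_values, dtype=float)
    if len(dp_values) < 5:
        raise UndefinedStatisticError("group DP test needs >= 5 datasets")
    diffs = dp_values - null
    median = float(np.median(dp_values))
    frac = (float(np.mean(significant)) if significant is not None else np.nan)
    if np.all(diffs == 0):
        return median, 1.0, frac
    nz = diffs[diffs != 0]
    method = "exact" if (len(nz) <= 25 and len(np.unique(np.abs(nz))) ==
                         len(nz)) else "approx"
    res = stats.wilcoxon(nz, alternative="less", method=method)
    return median, float(res.pvalue), frac


def cohens_d(values_neg, values_pos) -> float:
    """Cohen's d with pooled SD, oriented as (negative - positive) condition
    (miss - hit / attend-out - attend-in)."""
    x1 = np.asarray(values_neg, float)
    x2 = np.asarray(values_pos, float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    s2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    if s2 == 0:
        raise UndefinedStatisticError("zero pooled variance: d is infinite")
    return float((x1.mean() - x2.mean()) / np.sqrt(s2))


def pooled_condition_test(values_by_dataset, labels_by_dataset):
    """Pooled-average comparison across datasets.

    For each dataset, the feature is averaged per condition (NaN trials
    excluded); a right-tailed paired t-test then asks whether the
    negative-condition mean exceeds the positive-condition mean across
    datasets. Returns a dict with per-dataset means, grand means +/- SEM, the
    one-tailed p and Cohen's d of the paired condition means.
    """
    if len(values_by_dataset) < 2:
        raise UndefinedStatisticError("pooled test needs >= 2 datasets")
    neg_means, pos_means = [], []
    for values, labels in zip(values_by_dataset, labels_by_dataset):
        values = np.asarray(values, float)
        labels = np.asarray(labels, bool)
        ok = ~np.isnan(values)
        neg_means.append(values[ok & ~labels].mean())
        pos_means.append(values[ok & labels].mean())
    neg = np.array(neg_means)
    pos = np.array(pos_means)
    t = stats.ttest_rel(neg, pos, alternative="greater")
    sem = lambda x: x.std(ddof=1) / np.sqrt(len(x))  # noqa: E731
    return {
        "neg_means": neg, "pos_means": pos,
        "grand_neg": (neg.mean(), sem(neg)),
        "grand_pos": (pos.mean(), sem(pos)),
        "t": float(t.statistic), "p": float(t.pvalue),
        "d": cohens_d(neg, pos),
    }


def pcm_rate_curve(fvs, bin_width: int = 21, n_points: int = 100,
                   seed: int = 0):
    """Sliding positive-class-rate curve vs feature percentile, as percent
    change from mean (PCM), averaged across datasets.

    Per dataset: trials are sorted ascending by feature (ties broken by a
    seeded shuffle), the positive rate is computed in boxcar windows of
    ``bin_width`` trials sliding one trial at a time, converted to PCM
    = 100 * (rate - mean rate) / mean rate, then linearly resampled to
    ``n_points`` points. Returns ``(percentiles, mean_curve, sem_curve)``.
    """
    if isinstance(fvs, FeatureVector):
        fvs = [fvs]
    rng = np.random.default_rng(seed)
    curves = []
    for fv in fvs:
        values, labels = fv.defined()
        n = len(values)
        if n < bin_width + 1:
            raise ValueError(
                f"{fv.dataset_id}: need more than {bin_width} trials")
        order = np.lexsort((rng.random(n), values))  # seeded tie shuffle
        sorted_labels = labels[order].astype(float)
        rates = np.convolve(sorted_labels, np.ones(bin_width), "valid") / bin_width
        mean_rate = labels.mean()
        if mean_rate == 0:
            raise UndefinedStatisticError("mean positive rate is 0; PCM undefined")
        pcm = 100.0 * (rates - mean_rate) / mean_rate
        x = np.linspace(0.0, 1.0, len(pcm))
        curves.append(np.interp(np.linspace(0.0, 1.0, n_points), x, pcm))
    curves = np.vstack(curves)
    mean = curves.mean(axis=0)
    sem = (curves.std(axis=0, ddof=1) / np.sqrt(len(curves))
           if len(curves) > 1 else np.zeros(n_points))
    return np.linspace(0.0, 100.0, n_points), mean, sem


def feature_power_correlations(feature_fvs_by_dataset, power_by_dataset,
                               reference: str = "event_number"):
    """Per-dataset Pearson r between each feature and trial mean band power,
    plus a Friedman test over features and Holm-corrected one-tailed
    signed-rank tests of ``reference`` against every other feature.

    ``feature_fvs_by_dataset`` is a list (datasets) of dicts name ->
    FeatureVector; ``power_by_dataset`` the matching per-trial power arrays.
    Returns ``(r_frame_dict, friedman_result, pairwise_dict)`` where
    ``r_frame_dict`` maps feature -> per-dataset r (NaN for zero-variance
    features, which are excluded pairwise with a warning entry).
    """
    names = list(feature_fvs_by_dataset[0].keys())
    if len(names) < 4:
        raise ValueError("need >= 4 features for the Friedman comparison")
    r = {name: [] for name in names}
    for fvs, power in zip(feature_fvs_by_dataset, power_by_dataset):
        power = np.asarray(power, float)
        for name in names:
            values = fvs[name].values
            ok = ~np.isnan(values)
            v, p = values[ok], power[ok]
            if len(v) < 3 or np.ptp(v) == 0 or np.ptp(p) == 0:
                r[name].append(np.nan)
            else:
                r[name].append(stats.pearsonr(v, p).statistic)
    r = {k: np.asarray(v) for k, v in r.items()}

    matrix = np.column_stack([r[name] for name in names])
    complete = ~np.isnan(matrix).any(axis=1)
    warnings = []
    if not complete.all():
        warnings.append(f"{(~complete).sum()} dataset(s) dropped from the "
                        "Friedman/pairwise tests (zero-variance feature)")
    matrix = matrix[complete]
    if np.allclose(matrix, matrix[:, :1]):
        friedman = {"chi2": 0.0, "df": len(names) - 1, "p": 1.0}
    else:
        f = stats.friedmanchisquare(*(matrix[:, j] for j in range(len(names))))
        friedman = {"chi2": float(f.statistic), "df": len(names) - 1,
                    "p": float(f.pvalue)}

    others = [nm for nm in names if nm != reference]
    ref_idx = names.index(reference)
    raw = []
    for nm in others:
        j = names.index(nm)
        diff = matrix[:, ref_idx] - matrix[:, j]
        if np.all(diff == 0):
            raw.append(1.0)
        else:
            raw.append(float(stats.wilcoxon(
                diff[diff != 0], alternative="greater").pvalue))
    adjusted = multipletests(raw, method="holm")[1] if raw else []
    pairwise = {nm: {"p_raw": pr, "p_holm": float(pa)}
                for nm, pr, pa in zip(others, raw, adjusted)}
    return r, friedman, {"pairwise": pairwise, "warnings": warnings}


def optimal_criterion(counts, labels) -> dict:
    """Optimal integer event-number criterion for predicting the negative
    class by (event number >= criterion).

    Scans criteria 1 .. max(count)+1 and returns the one maximizing
    TPR - FPR, where the classifier's positive class is the negative
    behavioral condition; ties go to the smallest criterion.
    """
    counts = np.asarray(counts)
    labels = np.asarray(labels, dtype=bool)
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if labels.all() or not labels.any():
        raise UndefinedStatisticError("both classes required")
    neg = ~labels
    best = None
    for criterion in range(1, counts.max() + 2):
        pred = counts >= criterion
        tpr = pred[neg].mean()
        fpr = pred[labels].mean()
        j = tpr - fpr
        if best is None or j > best["tpr_minus_fpr"] + 1e-12:
            best = {"criterion": criterion, "tpr": float(tpr),
                    "fpr": float(fpr), "tpr_minus_fpr": float(j)}
    return best


def match_histogram_trim(key_values, labels, kind: str = "event_count",
                         bin_ms: float = 20.0, window=(-1000.0, 0.0),
                         seed: int = 0):
    """Histogram-matched trial subset by random trimming.

    Only trials with a defined key (>= 1 event) enter. For
    ``kind='event_count'`` bins are the integer counts 1..max; for
    ``kind='most_recent_timing'`` bins are ``bin_ms``-wide, the first starting
    at ``window[0]``. Within each bin the larger condition is randomly
    down-sampled without replacement to the smaller one's size, so per-bin
    histograms are exactly equal across conditions afterwards.

    Returns ``(kept_indices, info)``; ``info`` holds the retained fraction and
    a flag when no bin is populated by both conditions.
    """
    key_values = np.asarray(key_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    eligible = np.flatnonzero(~np.isnan(key_values))
    if kind == "event_count":
        eligible = eligible[key_values[eligible] >= 1]
        bins = key_values[eligible].astype(int)
    elif kind == "most_recent_timing":
        bins = np.floor(
            (key_values[eligible] - window[0]) / bin_ms).astype(int)
    else:
        raise ValueError(f"unknown matching kind {kind!r}")

    kept = []
    for b in np.unique(bins):
        idx = eligible[bins == b]
        pos = idx[labels[idx]]
        neg = idx[~labels[idx]]
        k = min(len(pos), len(neg))
        if k == 0:
            continue
        kept.extend(rng.choice(pos, k, replace=False))
        kept.extend(rng.choice(neg, k, replace=False))
    kept = np.sort(np.array(kept, dtype=int))
    info = {
        "retained_fraction": len(kept) / max(len(eligible), 1),
        "n_eligible": int(len(eligible)),
        "empty_intersection": len(kept) == 0,
    }
    return kept, info
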