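"""Epoch containers, file formats, run configuration and the pipeline driver.

The on-disk epoch format is a small HDF5 schema (datasets: ``data``, ``labels``;
attrs: ``fs``, ``t0_ms``, ``t1_ms``, ``dataset_id``, ``positive_label`` plus
free-form provenance) with a plain CSV + sidecar-JSON fallback for environments
where binary containers are unwanted. Times are milliseconds relative to
stimulus onset; the prestimulus window is negative, [-1000, 0] by default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("betaevents")

DEFAULT_BAND = (15.0, 29.0)       # beta band, Hz, inclusive
DEFAULT_CUTOFF_FOM = 6.0          # event power cutoff, factors of median
DEFAULT_M_CYCLES = 7.0            # Morlet wavelet constant
DEFAULT_WINDOW = (-1000.0, 0.0)   # analysis window, ms relative to stimulus
DEFAULT_TRIM = (-900.0, -100.0)   # edge-trimmed reporting window, ms


class ValidationError(ValueError):
    """Raised when a file or container violates the epoch schema."""


@dataclass
class EpochSet:
    """Trial-epoched single-channel time series with behavior labels.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_samples)
        One channel, one row per trial.
    fs : float
        Sampling rate in Hz.
    t0, t1 : float
        Window edges in ms relative to stimulus onset (t0 < t1 <= 0 for
        prestimulus data). Sample k sits at ``t0 + k / fs * 1000``.
    labels : ndarray of str, shape (n_trials,)
        Per-trial binary behavior label.
    positive_label : str
        The label value treated as the positive class (detected / attend-in).
    dataset_id : str
        Subject or session identifier; normalization never pools across ids.
    attrs : dict
        Free-form provenance (generator spec, seeds, processing history).
    """

    data: np.ndarray
    fs: float
    t0: float
    t1: float
    labels: np.ndarray
    positive_label: str
    dataset_id: str = "dataset"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (trials x samples)")
        if len(self.labels) != self.n_trials:
            raise ValidationError(
                f"labels length {len(self.labels)} != n_trials {self.n_trials}"
            )
        expected = (self.t1 - self.t0) / 1000.0 * self.fs
        if abs(self.n_samples - expected) > 1.0:
            raise ValidationError(
                f"n_samples {self.n_samples} inconsistent with window "
                f"[{self.t0}, {self.t1}] ms at fs {self.fs}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs * 1000.0

    @property
    def positive_mask(self) -> np.ndarray:
        return self.labels == self.positive_label

    def behavior_table(self) -> pd.DataFrame:
        """Per-trial label table aligned to the epoch rows."""
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "label": self.labels,
                "positive": self.positive_mask,
            }
        )


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the published analysis constants."""

    band: tuple = DEFAULT_BAND
    cutoff_fom: float = DEFAULT_CUTOFF_FOM
    m_cycles: float = DEFAULT_M_CYCLES
    window: tuple = DEFAULT_WINDOW
    trim: tuple = DEFAULT_TRIM
    fmin: float = 1.0
    fmax: float = 60.0
    pcm_bin: int = 21             # boxcar width (trials) for PCM curves
    timing_bin_ms: float = 20.0   # most-recent-event matching bin
    iei_bin_ms: float = 15.0      # IEI histogram bin (20 ms for comparisons)
    hist_window_ms: float = 50.0  # sliding occurrence-histogram window
    hist_step_ms: float = 1.0
    n_boot: int = 1000
    n_jitter: int = 1000
    amp_factor: float = 2.0       # Hilbert-amplitude cutoff factor
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["window"] = list(self.window)
        d["trim"] = list(self.trim)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a ``key = value`` declarative config file."""
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise ValidationError(f"unknown config key: {key}")
            kwargs[key] = json.loads(value.strip())
        for key in ("band", "window", "trim"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# epoch file round trip
# ---------------------------------------------------------------------------

_REQUIRED_DATASETS = ("data", "labels")
_REQUIRED_ATTRS = ("fs", "t0_ms", "t1_ms", "dataset_id", "positive_label")


def write_epochs(path, epochs: EpochSet) -> None:
    """Write an :class:`EpochSet` to the HDF5 epoch schema."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "labels", data=np.asarray(epochs.labels, dtype="S")
        )
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["t0_ms"] = float(epochs.t0)
        f.attrs["t1_ms"] = float(epochs.t1)
        f.attrs["dataset_id"] = epochs.dataset_id
        f.attrs["positive_label"] = epochs.positive_label
        f.attrs["provenance"] = json.dumps(epochs.attrs, default=str)


def read_epochs(path) -> EpochSet:
    """Read an epoch file, validating the schema; returns the EpochSet
    (behavior labels included; use :meth:`EpochSet.behavior_table`)."""
    path = Path(path)
    if path.suffix == ".csv":
        return _read_epochs_csv(path)
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED_DATASETS if k not in f]
        missing += [k for k in _REQUIRED_ATTRS if k not in f.attrs]
        if missing:
            raise ValidationError(
                f"{path} does not match the epoch schema; missing: {missing}"
            )
        attrs = json.loads(f.attrs.get("provenance", "{}"))
        return EpochSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            t0=float(f.attrs["t0_ms"]),
            t1=float(f.attrs["t1_ms"]),
            labels=f["labels"][()].astype(str),
            positive_label=str(f.attrs["positive_label"]),
            dataset_id=str(f.attrs["dataset_id"]),
            attrs=attrs,
        )


def write_epochs_csv(path, epochs: EpochSet) -> None:
    """CSV fallback: trials x samples numeric grid + sidecar JSON metadata."""
    path = Path(path)
    np.savetxt(path, epochs.data, delimiter=",")
    meta = {
        "fs": epochs.fs,
        "t0_ms": epochs.t0,
        "t1_ms": epochs.t1,
        "labels": list(map(str, epochs.labels)),
        "positive_label": epochs.positive_label,
        "dataset_id": epochs.dataset_id,
        "provenance": epochs.attrs,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, default=str))


def _read_epochs_csv(path: Path) -> EpochSet:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValidationError(f"CSV epoch file {path} lacks sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [
        k
        for k in ("fs", "t0_ms", "t1_ms", "labels", "positive_label")
        if k not in meta
    ]
    if missing:
        raise ValidationError(f"{sidecar} missing fields: {missing}")
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return EpochSet(
        data=data,
        fs=float(meta["fs"]),
        t0=float(meta["t0_ms"]),
        t1=float(meta["t1_ms"]),
        labels=np.asarray(meta["labels"]),
        positive_label=str(meta["positive_label"]),
        dataset_id=str(meta.get("dataset_id", "dataset")),
        attrs=meta.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, epochs, out_dir) -> dict:
    """Run the full analysis chain on one or more datasets.

    TFR -> factor-of-median normalization -> event detection (both
    definitions) -> trial summaries -> behavior statistics -> temporal
    statistics -> rhythmicity, writing every table under ``out_dir`` plus a
    manifest with the config hash and seeds. Across-dataset tests (signed
    rank, pooled averages, Friedman) run only when >= 5 datasets are given;
    otherwise they are skipped and noted in the manifest.

    Returns the manifest dict.
    """
    from . import behavior, events, rhythmicity, temporal, tfr

    if isinstance(epochs, EpochSet):
        epochs = [epochs]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "datasets": [e.dataset_id for e in epochs],
        "outputs": [],
        "log": [],
    }

    def note(msg):
        logger.info(msg)
        manifest["log"].append(msg)

    def write_tsv(name, frame):
        p = out_dir / name
        frame.to_csv(p, sep="\t", index=False, float_format="%.10g")
        manifest["outputs"].append(name)

    freqs = np.arange(config.fmin, config.fmax + 0.5, 1.0)
    per_ds = []
    for ep in epochs:
        note(f"dataset {ep.dataset_id}: {ep.n_trials} trials")
        raw = tfr.morlet_tfr(ep, freqs, m=config.m_cycles)
        fom = tfr.fom_normalize(raw)
        scalar, series = tfr.band_mean_power(fom, config.band, config.window,
                                             trim=config.trim)
        evs = events.detect_events(fom, config.band, config.cutoff_fom)
        summaries = events.summarize_trials(evs, ep.n_trials, config.window)
        regions = events.detect_nonoverlapping(fom, config.band,
                                               config.cutoff_fom)
        ds = {
            "epochs": ep, "tfr": fom, "power": scalar, "series": series,
            "events": evs, "summaries": summaries, "regions": regions,
        }
        per_ds.append(ds)
        tag = ep.dataset_id
        write_tsv(f"{tag}_events.tsv", events.events_frame(evs))
        write_tsv(f"{tag}_nonoverlap.tsv", events.nonoverlapping_frame(regions))
        write_tsv(f"{tag}_summaries.tsv", events.summaries_frame(summaries))
        n_zero = sum(1 for s in summaries if s.n_events == 0)
        note(f"dataset {tag}: {len(evs)} events; {n_zero} zero-event trials "
             "excluded from event-conditional features")

    # per-dataset behavior statistics
    dp_rows = []
    rng = np.random.default_rng(config.seed)
    for ds in per_ds:
        ep = ds["epochs"]
        fvs = behavior.feature_vectors(ds["summaries"], ds["power"],
                                       ep.positive_mask, ep.dataset_id)
        for name, fv in fvs.items():
            try:
                res = behavior.detect_probability(
                    fv, n_boot=config.n_boot,
                    seed=int(rng.integers(2**31 - 1)))
            except behavior.UndefinedStatisticError:
                note(f"dataset {ep.dataset_id}: DP undefined for {name}")
                continue
            dp_rows.append({
                "dataset": ep.dataset_id, "feature": name, "dp": res.dp,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "n": res.n, "significant": res.significant_below_half,
            })
    dp_frame = pd.DataFrame(dp_rows)
    write_tsv("dp.tsv", dp_frame)

    summary = {"config_hash": config.hash(), "seed": config.seed}
    if len(per_ds) >= 5:
        group = {}
        for name in sorted(dp_frame["feature"].unique()):
            vals = dp_frame.loc[dp_frame["feature"] == name, "dp"].to_numpy()
            med, p, frac = behavior.group_dp_test(vals)
            group[name] = {"median_dp": med, "p": p, "frac_significant": frac}
        summary["group_dp"] = group
    else:
        note("fewer than 5 datasets: across-dataset tests skipped")

    # temporal statistics
    ff_cv = []
    for ds in per_ds:
        ep = ds["epochs"]
        counts = np.array([s.n_events for s in ds["summaries"]])
        by_trial = temporal.event_times_by_trial(ds["events"], ep.n_trials)
        ieis = temporal.inter_event_intervals(by_trial)
        row = {"dataset": ep.dataset_id,
               "fano": temporal.fano_factor(counts) if counts.mean() > 0
               else np.nan,
               "cv2": temporal.cv2(ieis) if len(ieis) >= 2 else np.nan}
        ff_cv.append(row)
    write_tsv("burstiness.tsv", pd.DataFrame(ff_cv))

    if len(per_ds) >= 5:
        hist = temporal.event_time_histogram(
            [temporal.event_times_by_trial(d["events"], d["epochs"].n_trials)
             for d in per_ds],
            [d["epochs"].positive_mask for d in per_ds],
            window=config.window, trim=config.trim,
            win_ms=config.hist_window_ms, step_ms=config.hist_step_ms)
        write_tsv("event_time_histogram.tsv", temporal.histogram_frame(hist))

    # rhythmicity
    rhythm_rows = []
    for ds in per_ds:
        ep = ds["epochs"]
        try:
            res = rhythmicity.generator_analysis(
                ep, band=config.band, amp_factor=config.amp_factor,
                seed=config.seed)
        except rhythmicity.InsufficientStructureError as exc:
            note(f"dataset {ep.dataset_id}: rhythmicity skipped ({exc})")
            continue
        rhythm_rows.append({
            "dataset": ep.dataset_id,
            "period_ms": res.period_ms,
            "cutoff": res.cutoff,
            "supra_fraction": res.supra_fraction,
            "chi2_p_above": res.stats["above"]["chi2_p"],
            "chi2_p_below": res.stats["below"]["chi2_p"],
            "resultant_below": res.stats["below"]["resultant"],
            "classification": rhythmicity.classify_generator(res),
        })
    write_tsv("rhythmicity.tsv", pd.DataFrame(rhythm_rows))

    summary["burstiness"] = ff_cv
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     default=float))
    manifest["outputs"].append("summary.json")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
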