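"""Writing-tablet kinematics: from raw pen trajectories to trial outcomes.

Each trial is a sequence of loops written between visual target lines on a
digitising tablet (200 Hz).  Four outcomes summarise a trial:

* ``amplitude_pct`` - mean vertical stroke height as % of the target size,
* ``cov_ampl_pct``  - coefficient of variation of stroke heights (%),
* ``speed_cm_s``    - path length divided by trial duration,
* ``deviation_pct`` - ``|100 - amplitude_pct|``, the accuracy outcome.

Traces are low-pass filtered at 7 Hz (4th-order Butterworth, zero-phase)
before stroke extraction; strokes are the segments between alternating local
extrema of the vertical coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

FILTER_CUTOFF_HZ = 7.0
FILTER_ORDER = 4
#: extrema with prominence below this fraction of the target size are noise
PROMINENCE_FRAC = 0.05


@dataclass
class WritingTrial:
    """A timestamped pen trajectory with task metadata."""

    t: np.ndarray          # seconds, strictly increasing
    x: np.ndarray          # cm
    y: np.ndarray          # cm
    target_cm: float       # 0.6 (small) or 1.0 (large)
    condition: str = "single"     # single | dual
    timepoint: str = "pre"        # pre | post | followup
    subject: str = "s01"
    run: int = 1

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must be equal length")
        if self.t.size >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.target_cm <= 0:
            raise ValueError("target size must be positive")

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @classmethod
    def from_csv(cls, path, **meta) -> "WritingTrial":
        df = pd.read_csv(path)
        return cls(df["t_s"].to_numpy(), df["x_cm"].to_numpy(),
                   df["y_cm"].to_numpy(), **meta)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, "x_cm": self.x, "y_cm": self.y}).to_csv(
            path, index=False)


@dataclass
class TrialMetrics:
    amplitude_pct: float
    cov_ampl_pct: float
    speed_cm_s: float
    deviation_pct: float
    n_strokes: int


def filter_trace(trial: WritingTrial, cutoff_hz: float = FILTER_CUTOFF_HZ,
                 order: int = FILTER_ORDER) -> WritingTrial:
    """Zero-phase (forward-backward) Butterworth low-pass of x and y."""
    fs = trial.fs_hz
    if fs <= 2 * cutoff_hz:
        raise ValueError(f"sampling rate {fs:.1f} Hz too low for {cutoff_hz} Hz cutoff")
    sos = signal.butter(order, cutoff_hz, fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if trial.t.size <= padlen:
        raise ValueError("trace shorter than the filter warm-up length")
    return replace(trial,
                   x=signal.sosfiltfilt(sos, trial.x),
                   y=signal.sosfiltfilt(sos, trial.y))


def extract_strokes(trial: WritingTrial,
                    prominence_frac: float = PROMINENCE_FRAC) -> np.ndarray:
    """Per-stroke heights (cm) from alternating local extrema of y.

    Maxima and minima with prominence of at least ``prominence_frac`` of the
    target size are merged into one alternating sequence (runs of same-type
    extrema keep the most extreme); each consecutive pair defines a stroke
    whose height is the absolute vertical difference.  Partial segments before
    the first and after the last extremum are discarded.
    """
    y = trial.y
    prom = prominence_frac * trial.target_cm
    peaks, _ = signal.find_peaks(y, prominence=prom)
    troughs, _ = signal.find_peaks(-y, prominence=prom)
    kinds = np.concatenate([np.ones(peaks.size, int), -np.ones(troughs.size, int)])
    locs = np.concatenate([peaks, troughs])
    order = np.argsort(locs)
    locs, kinds = locs[order], kinds[order]
    # enforce alternation: within a run of the same type keep the most extreme
    keep_locs: list = []
    keep_kinds: list = []
    for loc, kind in zip(locs, kinds):
        if keep_kinds and keep_kinds[-1] == kind:
            prev = keep_locs[-1]
            if (kind == 1 and y[loc] > y[prev]) or (kind == -1 and y[loc] < y[prev]):
                keep_locs[-1] = loc
        else:
            keep_locs.append(loc)
            keep_kinds.append(kind)
    if len(keep_locs) < 2:
        raise ValueError("no strokes detected (fewer than 2 retained extrema)")
    ext = y[np.asarray(keep_locs)]
    return np.abs(np.diff(ext))


def trial_metrics(strokes: np.ndarray, trial: WritingTrial) -> TrialMetrics:
    """The four trial outcomes from per-stroke heights and the (filtered) trace."""
    strokes = np.asarray(strokes, dtype=float)
    if strokes.size < 1:
        raise ValueError("need at least one stroke")
    mean_h = strokes.mean()
    if mean_h == 0:
        raise ValueError("mean stroke height is 0; CV undefined")
    amplitude = 100.0 * mean_h / trial.target_cm
    cov = 100.0 * strokes.std(ddof=1) / mean_h if strokes.size > 1 else 0.0
    path = np.sum(np.hypot(np.diff(trial.x), np.diff(trial.y)))
    speed = path / (trial.t[-1] - trial.t[0])
    return TrialMetrics(
        amplitude_pct=float(amplitude),
        cov_ampl_pct=float(cov),
        speed_cm_s=float(speed),
        deviation_pct=float(abs(100.0 - amplitude)),
        n_strokes=int(strokes.size),
    )


def process_trial(trial: WritingTrial, cutoff_hz: float = FILTER_CUTOFF_HZ,
                  order: int = FILTER_ORDER,
                  prominence_frac: float = PROMINENCE_FRAC) -> TrialMetrics:
    """Filter, extract strokes, and compute outcomes for one trial."""
    filtered = filter_trace(trial, cutoff_hz=cutoff_hz, order=order)
    heights = extract_strokes(filtered, prominence_frac=prominence_frac)
    return trial_metrics(heights, filtered)


def metrics_row(trial: WritingTrial, m: TrialMetrics) -> dict:
    return {
        "subject": trial.subject, "timepoint": trial.timepoint,
        "condition": trial.condition, "target_cm": trial.target_cm,
        "run": trial.run, "amplitude_pct": m.amplitude_pct,
        "cov_ampl_pct": m.cov_ampl_pct, "speed_cm_s": m.speed_cm_s,
        "deviation_pct": m.deviation_pct, "n_strokes": m.n_strokes,
    }


def aggregate_runs(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of the outcomes over runs, per subject x timepoint x
    condition x target size."""
    keys = ["subject", "timepoint", "condition", "target_cm"]
    out = (trial_table
           .groupby(keys, as_index=False)
           [["amplitude_pct", "cov_ampl_pct", "speed_cm_s", "deviation_pct"]]
           .mean())
    return out


def process_directory(trials_dir, cutoff_hz: float = FILTER_CUTOFF_HZ,
                      order: int = FILTER_ORDER) -> pd.DataFrame:
    """Process every ``*.csv`` trial under a directory.

    Metadata is read from a ``trials.tsv`` sidecar (columns: file, subject,
    timepoint, condition, target_cm, run).
    """
    trials_dir = Path(trials_dir)
    sidecar = pd.read_csv(trials_dir / "trials.tsv", sep="\t")
    rows = []
    for rec in sidecar.itertuples(index=False):
        trial = WritingTrial.from_csv(
            trials_dir / rec.file, target_cm=rec.target_cm, subject=rec.subject,
            timepoint=rec.timepoint, condition=rec.condition, run=rec.run)
        rows.append(metrics_row(trial, process_trial(trial, cutoff_hz, order)))
    return pd.DataFrame(rows)
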