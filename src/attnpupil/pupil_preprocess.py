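"""Pupil preprocessing: blink interpolation, filtering, epoching, baselining.

The pipeline mirrors standard pupillometry practice: runs of invalid samples
(eye closures) are linearly interpolated with padding, the continuous trace
is low-pass filtered with a zero-phase Butterworth filter, epochs are cut
around cue onsets, and per-trial pre-cue baselines yield tonic statistics
(mean/SD of baselines) and phasic traces (baseline-corrected condition
averages, optionally z-scored by the tonic SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

PhasicMode = Literal["zscore", "subtract_only", "proportional"]


@dataclass
class SampleSeries:
    """A continuous, uniformly sampled pupil recording.

    ``valid`` flags samples where the tracker reported a pupil; invalid runs
    are blinks or other eye closures.
    """

    time: np.ndarray
    pupil: np.ndarray
    valid: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.time.size == self.pupil.size == self.valid.size):
            raise ValueError("time, pupil and valid must have equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            expected = 1.0 / self.sampling_rate
            if not np.allclose(dt, expected, rtol=1e-3, atol=1e-9):
                raise ValueError("sampling grid is not uniform at the stated rate")

    def __len__(self) -> int:
        return self.time.size

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(~self.valid)) if len(self) else 0.0

    def copy(self) -> "SampleSeries":
        return SampleSeries(self.time.copy(), self.pupil.copy(),
                            self.valid.copy(), self.sampling_rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "pupil": self.pupil,
                             "valid": self.valid.astype(int)})

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   sampling_rate: Optional[float] = None) -> "SampleSeries":
        t = df["time_s"].to_numpy(dtype=float)
        if sampling_rate is None:
            sampling_rate = 1.0 / np.median(np.diff(t))
        return cls(time=t, pupil=df["pupil"].to_numpy(dtype=float),
                   valid=df["valid"].to_numpy() != 0,
                   sampling_rate=float(sampling_rate))


@dataclass
class EpochSet:
    """Per-trial epochs time-locked to cue onset."""

    epochs: np.ndarray                 # trials x time
    epoch_time: np.ndarray             # seconds relative to cue onset
    trial_labels: pd.DataFrame         # room, interrupted (+ any passthrough)
    missing_fraction: np.ndarray       # per trial, pre-interpolation
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.epochs.shape[0] != len(self.trial_labels):
            raise ValueError("epoch rows must align with trial_labels")
        if self.epochs.shape[1] != self.epoch_time.size:
            raise ValueError("epoch columns must align with epoch_time")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


@dataclass
class BaselineStats:
    """Pre-cue baseline summary: per-trial means and tonic statistics."""

    per_trial_baseline: np.ndarray
    tonic_mean: float
    tonic_sd: float

    def __post_init__(self) -> None:
        if self.tonic_sd < 0:
            raise ValueError("tonic_sd must be >= 0")


@dataclass
class PhasicTrace:
    """A condition-averaged, baseline-normalized pupil time course."""

    trace: np.ndarray
    epoch_time: np.ndarray
    mode: PhasicMode
    n_trials_averaged: int


# ---------------------------------------------------------------------------
# Blink handling
# ---------------------------------------------------------------------------

def find_invalid_runs(series: SampleSeries) -> list[tuple[int, int]]:
    """Maximal runs of invalid samples as half-open index intervals."""
    invalid = ~series.valid
    if not invalid.any():
        return []
    padded = np.concatenate([[False], invalid, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def interpolate_blinks(series: SampleSeries, pre_pad: float = 0.050,
                       post_pad: float = 0.150) -> SampleSeries:
    """Linearly interpolate padded blink intervals.

    Each invalid run is padded by ``pre_pad`` seconds before and ``post_pad``
    after; overlapping padded intervals are merged, then each merged interval
    is replaced by the straight line between its boundary samples.  Intervals
    touching a recording edge are filled by holding the nearest valid value.
    All samples are marked valid afterwards.
    """
    runs = find_invalid_runs(series)
    out = series.copy()
    if not runs:
        return out
    n = len(series)
    if len(runs) == 1 and runs[0] == (0, n):
        raise ValueError("series is fully invalid; nothing to anchor on")
    fs = series.sampling_rate
    pre = int(round(pre_pad * fs))
    post = int(round(post_pad * fs))
    padded = _merge_intervals([(max(0, a - pre), min(n, b + post))
                               for a, b in runs])
    for a, b in padded:
        if a == 0 and b == n:
            raise ValueError("padded blink covers the entire recording")
        if a == 0:
            out.pupil[:b] = out.pupil[b]
        elif b == n:
            out.pupil[a:] = out.pupil[a - 1]
        else:
            left, right = out.pupil[a - 1], out.pupil[b]
            # line through the two anchor samples
            out.pupil[a:b] = left + (right - left) * (
                np.arange(1, b - a + 1) / (b - a + 1))
    out.valid[:] = True
    return out


# ---------------------------------------------------------------------------
# Filtering and epoching
# ---------------------------------------------------------------------------

def lowpass(series: SampleSeries, order: int = 4, cutoff: float = 10.0) -> SampleSeries:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    nyquist = series.sampling_rate / 2
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyquist} Hz")
    if not series.valid.all():
        raise ValueError("filter requires a fully valid series; interpolate first")
    b, a = butter(order, cutoff / nyquist)
    out = series.copy()
    out.pupil = filtfilt(b, a, out.pupil)
    return out


def epoch(series: SampleSeries, cue_onsets: Sequence[float],
          window: tuple[float, float] = (-1.0, 7.0),
          trial_labels: Optional[pd.DataFrame] = None,
          raw_valid: Optional[np.ndarray] = None) -> EpochSet:
    """Cut per-trial epochs time-locked to cue onsets.

    The window is half-open: a [-1, 7) s window at 1000 Hz yields 8000
    samples.  ``raw_valid`` (pre-interpolation validity flags) feeds the
    per-trial missing fractions.
    """
    fs = series.sampling_rate
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must be increasing")
    n_samp = int(round((w1 - w0) * fs))
    t0 = series.time[0]
    valid_src = series.valid if raw_valid is None else np.asarray(raw_valid, bool)

    rows, missing = [], []
    for k, cue in enumerate(cue_onsets):
        i0 = int(round((cue + w0 - t0) * fs))
        i1 = i0 + n_samp
        if i0 < 0 or i1 > len(series):
            raise ValueError(
                f"trial {k}: epoch window [{cue + w0:.3f}, {cue + w1:.3f}) s "
                "exceeds recording bounds")
        rows.append(series.pupil[i0:i1])
        missing.append(float(np.mean(~valid_src[i0:i1])))

    if trial_labels is None:
        trial_labels = pd.DataFrame(index=range(len(cue_onsets)))
    epoch_time = w0 + np.arange(n_samp) / fs
    return EpochSet(epochs=np.asarray(rows), epoch_time=epoch_time,
                    trial_labels=trial_labels.reset_index(drop=True),
                    missing_fraction=np.asarray(missing), sampling_rate=fs)


def exclude_high_missing(missing_by_subject: dict, threshold: float = 0.5
                         ) -> tuple[list, pd.DataFrame]:
    """Flag subjects whose overall missing-sample fraction exceeds *threshold*.

    Fractions are computed before interpolation.  The boundary is strict:
    a subject at exactly the threshold is retained.
    """
    rows = []
    retained = []
    for subject, frac in missing_by_subject.items():
        excluded = frac > threshold
        rows.append({"subject": subject, "missing_fraction": float(frac),
                     "excluded": bool(excluded)})
        if not excluded:
            retained.append(subject)
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Baselining
# ---------------------------------------------------------------------------

def baseline_stats(epochs: EpochSet,
                   baseline_window: tuple[float, float] = (-0.5, 0.0)
                   ) -> BaselineStats:
    """Per-trial baseline means and tonic mean/SD across all trials.

    The baseline window is closed-open: the sample at cue onset belongs to
    the stimulus, not the baseline.  The SD uses the n-1 estimator.
    """
    b0, b1 = baseline_window
    sel = (epochs.epoch_time >= b0) & (epochs.epoch_time < b1)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    per_trial = epochs.epochs[:, sel].mean(axis=1)
    sd = float(np.std(per_trial, ddof=1)) if per_trial.size > 1 else 0.0
    return BaselineStats(per_trial_baseline=per_trial,
                         tonic_mean=float(per_trial.mean()),
                         tonic_sd=sd)


def phasic(epochs: EpochSet, baseline: BaselineStats,
           mode: PhasicMode = "zscore",
           trial_mask: Optional[np.ndarray] = None) -> PhasicTrace:
    """Condition-averaged, baseline-normalized trace.

    ``zscore``: average of baseline-subtracted epochs divided by the
    subject's tonic SD (across-trial SD of baselines).  ``subtract_only``:
    the average alone.  ``proportional``: average of per-trial
    ``(epoch - baseline) / baseline``.
    """
    if trial_mask is None:
        trial_mask = np.ones(epochs.n_trials, dtype=bool)
    trial_mask = np.asarray(trial_mask, dtype=bool)
    if not trial_mask.any():
        raise ValueError("no trials selected")
    sub = epochs.epochs[trial_mask] - baseline.per_trial_baseline[
        trial_mask, None]
    if mode == "zscore":
        if baseline.tonic_sd == 0:
            raise ValueError("degenerate baseline distribution: tonic_sd is 0")
        trace = sub.mean(axis=0) / baseline.tonic_sd
    elif mode == "subtract_only":
        trace = sub.mean(axis=0)
    elif mode == "proportional":
        trace = (sub / baseline.per_trial_baseline[trial_mask, None]).mean(axis=0)
    else:
        raise ValueError(f"unknown phasic mode {mode!r}")
    return PhasicTrace(trace=trace, epoch_time=epochs.epoch_time, mode=mode,
                       n_trials_averaged=int(trial_mask.sum()))
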