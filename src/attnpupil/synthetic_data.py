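"""Synthetic multi-subject pupil recordings and serial-recall responses.

The pupil generator is an additive event-kernel model: each stimulus event
(cue, syllable, interrupter) evokes an Erlang-shaped dilation whose amplitude
depends on the event class and the room condition; responses superpose on a
subject-specific tonic level with AR(1) measurement noise.  Blinks appear as
runs of invalid samples, as an eye tracker would report them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .pupil_preprocess import SampleSeries
from .trial_design import DesignConfig, StimulusSchedule, TrialSpec, build_schedule

DEFAULT_AMPLITUDES: dict[str, float] = {
    "cue": 0.04,
    "syllable_anechoic": 0.05,
    "syllable_reverberant": 0.03,
    "interrupter_anechoic": 0.25,
    "interrupter_reverberant": 0.25,
}


@dataclass(frozen=True)
class PupilGenParams:
    """Generative parameters for one cohort of synthetic pupil recordings."""

    sampling_rate: float = 100.0
    tonic_mean: float = 4.0
    tonic_sd: float = 0.5
    kernel_shape: float = 10.1
    kernel_peak_time: float = 0.93
    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    noise_sd: float = 0.02
    noise_ar1: float = 0.97
    blink_rate: float = 0.1
    blink_duration_mean: float = 0.15
    inter_trial_interval: float = 8.0
    epoch_window: tuple[float, float] = (-1.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must be in [0, 1)")


@dataclass(frozen=True)
class BehaviorGenParams:
    """Generative parameters for synthetic serial-recall responses.

    Per-cell correctness probabilities are
    ``base[pos] - interruption_penalty[pos]*interrupted - reverb_penalty*reverberant``,
    clipped to [1/3, 1] (chance on a 3-alternative set).
    """

    base_accuracy_by_position: tuple[float, ...] = (0.95, 0.78, 0.80, 0.88)
    interruption_penalty_by_position: tuple[float, ...] = (
        0.03, 0.12, 0.08, 0.04)
    reverb_penalty: float = 0.08
    seed: int = 0

    def cell_probability(self, position: int, interrupted: bool,
                         room: str) -> float:
        p = self.base_accuracy_by_position[position]
        if interrupted:
            p -= self.interruption_penalty_by_position[position]
        if room == "reverberant":
            p -= self.reverb_penalty
        if not 0 <= p <= 1:
            warnings.warn(
                f"cell probability {p:.3f} outside [0, 1]; clipping",
                stacklevel=2)
        return float(np.clip(p, 1 / 3, 1.0))


def pupil_kernel(t, n: float = 10.1, t_max: float = 0.93):
    """Erlang-form event-evoked response, normalized to unit peak at ``t_max``.

    ``h(t) = (t / t_max)**n * exp(n * (1 - t / t_max))`` for t >= 0, else 0.
    """
    if n <= 0 or t_max <= 0:
        raise ValueError("n and t_max must be > 0")
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(t > 0,
                     np.exp(n * (np.log(np.maximum(t, 1e-300) / t_max)
                                 + 1 - t / t_max)),
                     0.0)
    return h if h.ndim else float(h)


def trial_events(trial: TrialSpec, schedule: StimulusSchedule,
                 cue_time: float) -> list[tuple[float, str]]:
    """(absolute onset, amplitude key) pairs for one trial's events."""
    events = [(cue_time, "cue")]
    syl_key = f"syllable_{trial.room}"
    for onset in schedule.target_onsets:
        events.append((cue_time + onset, syl_key))
    for onset in schedule.distractor_onsets:
        events.append((cue_time + onset, syl_key))
    if schedule.interrupter_onset is not None:
        events.append((cue_time + schedule.interrupter_onset,
                       f"interrupter_{trial.room}"))
    return events


def _ar1_noise(rng: np.random.Generator, n: int, sd: float,
               rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation *sd*."""
    if sd == 0:
        return np.zeros(n)
    eps = rng.standard_normal(n) * sd * np.sqrt(1 - rho**2)
    eps[0] = rng.standard_normal() * sd
    from scipy.signal import lfilter
    out, _ = lfilter([1.0], [1.0, -rho], eps, zi=[0.0])
    return out


def _blink_mask(rng: np.random.Generator, n: int, fs: float, rate: float,
                mean_dur: float) -> np.ndarray:
    """Invalid-sample mask from a Poisson blink process."""
    mask = np.zeros(n, dtype=bool)
    if rate <= 0:
        return mask
    total_t = n / fs
    t = rng.exponential(1 / rate)
    while t < total_t:
        dur = rng.exponential(mean_dur)
        i0 = int(round(t * fs))
        i1 = min(n, i0 + max(1, int(round(dur * fs))))
        mask[i0:i1] = True
        t += dur + rng.exponential(1 / rate)
    return mask


def simulate_subject(
    design: Sequence[TrialSpec],
    config: DesignConfig,
    params: PupilGenParams,
    seed: Optional[int] = None,
) -> tuple[SampleSeries, pd.DataFrame]:
    """Generate one subject's continuous pupil recording plus its event table.

    The event table has columns ``trial, cue_onset_s, room, interrupted``.
    Cue onsets are spaced ``params.inter_trial_interval`` apart, which must be
    wide enough that analysis epochs do not overlap.
    """
    w0, w1 = params.epoch_window
    if params.inter_trial_interval < (w1 - w0):
        raise ValueError(
            "inter_trial_interval shorter than the epoch span: epochs overlap")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    fs = params.sampling_rate
    n_trials = len(design)
    pre_roll = max(1.5, -w0 + 0.5)
    total_t = pre_roll + (n_trials - 1) * params.inter_trial_interval + w1 + 1.0
    n = int(round(total_t * fs))
    time = np.arange(n) / fs

    tonic = params.tonic_mean + params.tonic_sd * rng.standard_normal()
    pupil = np.full(n, tonic)

    # kernel support: long enough that the tail is negligible
    support = np.arange(int(round(6.0 * params.kernel_peak_time * fs))) / fs
    kernel = pupil_kernel(support, params.kernel_shape, params.kernel_peak_time)

    cue_times = pre_roll + np.arange(n_trials) * params.inter_trial_interval
    events_rows = []
    for trial, cue_t in zip(design, cue_times):
        sched = build_schedule(trial, config)
        for onset, key in trial_events(trial, sched, cue_t):
            amp = params.amplitudes[key]
            if amp == 0:
                continue
            i0 = int(round(onset * fs))
            seg = kernel[: n - i0]
            pupil[i0:i0 + seg.size] += amp * seg
        events_rows.append({
            "trial": trial.trial_index,
            "cue_onset_s": float(cue_t),
            "room": trial.room,
            "interrupted": int(trial.interrupted),
        })

    pupil = pupil + _ar1_noise(rng, n, params.noise_sd, params.noise_ar1)
    mask = _blink_mask(rng, n, fs, params.blink_rate,
                       params.blink_duration_mean)
    valid = ~mask
    pupil = pupil.copy()
    pupil[mask] = 0.0  # tracker reports no size during closures

    series = SampleSeries(time=time, pupil=pupil, valid=valid,
                          sampling_rate=fs)
    return series, pd.DataFrame(events_rows)


def simulate_behavior(
    design: Sequence[TrialSpec],
    params: BehaviorGenParams,
    subject: int = 0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-position recall responses for one subject.

    Each position is recalled correctly with the cell probability; otherwise
    the response is drawn uniformly from the two other syllables.  Columns:
    ``subject, trial, position, target, response``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    for trial in design:
        for pos, target in enumerate(trial.target_syllables):
            p = params.cell_probability(pos, trial.interrupted, trial.room)
            if rng.random() < p:
                response = target
            else:
                others = [s for s in ("ba", "da", "ga") if s != target]
                response = others[rng.integers(2)]
            rows.append({
                "subject": subject,
                "trial": trial.trial_index,
                "position": pos,
                "target": target,
                "response": response,
            })
    return pd.DataFrame(rows)
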