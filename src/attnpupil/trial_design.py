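"""Experiment design: power analysis, trial/block construction, stimulus schedules.

The design models a two-stream spatial selective-attention experiment: on each
trial a spatial cue is followed by two temporally interleaved syllable streams
(target and distractor), with an optional brief interrupter shortly before the
second target syllable.  Trials are organised in blocks with exact
counterbalancing of the interruption and target-side factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

SYLLABLE_SET = ("ba", "da", "ga")

Room = Literal["anechoic", "reverberant"]
Side = Literal["left", "right"]
BlockingMode = Literal["by_room", "by_interruption"]


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Parameters of a prospective power analysis for a paired-sample t-test."""

    effect_size_d: float = 0.37
    alpha: float = 0.05
    power: float = 0.8
    tails: Literal["two", "one"] = "two"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must be in (0, 1), got {self.power}")
        if self.effect_size_d == 0:
            raise ValueError("undetectable effect: effect_size_d is zero")
        if self.effect_size_d < 0:
            raise ValueError("effect_size_d must be positive")
        if self.power <= self.alpha:
            raise ValueError("requested power must exceed alpha")


def paired_t_power(n: float, d: float, alpha: float = 0.05,
                   tails: str = "two") -> float:
    """Exact power of a paired-sample t-test with *n* pairs at effect size *d*.

    Uses the noncentral t distribution with noncentrality ``d * sqrt(n)`` and
    ``n - 1`` degrees of freedom.
    """
    df = n - 1.0
    if df <= 0:
        return 0.0
    ncp = d * np.sqrt(n)
    if tails == "two":
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, ncp)
                     + stats.nct.cdf(-tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tcrit, df, ncp))


def required_sample_size(spec: PowerSpec) -> int:
    """Whole-participant sample size achieving the requested power.

    Solves the continuous noncentral-t power equation for n and rounds the
    solution to the nearest integer.
    """
    d, alpha, target = spec.effect_size_d, spec.alpha, spec.power

    def gap(n: float) -> float:
        return paired_t_power(n, d, alpha, spec.tails) - target

    # integer scan for a bracket: power is monotone increasing in n
    hi = 2
    while gap(hi) < 0:
        hi += 1
        if hi > 1_000_000:
            raise ValueError("sample size exceeds 1e6; check parameters")
    if hi == 2:
        return 2
    n_cont = optimize.brentq(gap, hi - 1, hi)
    return int(round(n_cont))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignConfig:
    """Trial/block structure and stimulus timing parameters.

    Times are in seconds.  ``interrupter_lead`` is the interval by which the
    interrupter onset precedes the onset of the second target-stream syllable.
    ``cue_duration`` defaults to one syllable duration (the cue is a single
    spatialized syllable).
    """

    n_trials: int = 160
    n_blocks: int = 8
    blocking_mode: BlockingMode = "by_room"
    syllables_per_stream: int = 4
    syllable_duration: float = 0.450
    intersyllable_gap: float = 0.150
    lead_onset_after_cue: float = 0.500
    stream_lag: float = 0.300
    interrupter_duration: float = 0.250
    interrupter_lead: float = 0.125
    leading_side: Side = "left"
    cue_duration: Optional[float] = None
    first_room: Room = "anechoic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials % self.n_blocks:
            raise ValueError("n_trials must be divisible by n_blocks")
        if self.syllables_per_stream < 2:
            raise ValueError("need at least 2 syllables per stream")
        for name in ("syllable_duration", "intersyllable_gap",
                     "lead_onset_after_cue", "stream_lag",
                     "interrupter_duration", "interrupter_lead"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.cue_duration is None:
            object.__setattr__(self, "cue_duration", self.syllable_duration)

    @property
    def trials_per_block(self) -> int:
        return self.n_trials // self.n_blocks


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int
    block_index: int
    room: Room
    interrupted: bool
    target_side: Side
    target_leading: bool
    target_syllables: tuple[str, ...]


@dataclass(frozen=True)
class StimulusSchedule:
    """Absolute event times in seconds, with t = 0 at cue onset.

    ``cue_offset_time`` is the time the cue ends; stream onsets are measured
    from there by construction but stored on the cue-onset clock.
    """

    cue_offset_time: float
    target_onsets: tuple[float, ...]
    distractor_onsets: tuple[float, ...]
    interrupter_onset: Optional[float] = None

    def merged_onsets(self) -> np.ndarray:
        return np.sort(np.concatenate([self.target_onsets,
                                       self.distractor_onsets]))

    def shifted(self, offset: float) -> "StimulusSchedule":
        return StimulusSchedule(
            cue_offset_time=self.cue_offset_time + offset,
            target_onsets=tuple(t + offset for t in self.target_onsets),
            distractor_onsets=tuple(t + offset for t in self.distractor_onsets),
            interrupter_onset=(None if self.interrupter_onset is None
                               else self.interrupter_onset + offset),
        )


def _counterbalanced_pairs(values_a: Sequence, values_b: Sequence,
                           count: int) -> list[tuple]:
    """Full cross of two binary factors repeated to *count* items."""
    cross = [(a, b) for a in values_a for b in values_b]
    if count % len(cross):
        raise ValueError(
            f"cannot counterbalance {len(cross)} cells into {count} trials")
    return cross * (count // len(cross))


def build_design(config: DesignConfig) -> list[TrialSpec]:
    """Construct the full, counterbalanced trial list.

    With ``blocking_mode='by_room'`` the room condition is constant within a
    block and alternates across blocks, while interruption and target side are
    exactly counterbalanced within every block.  With ``'by_interruption'``
    the interruption status is block-constant (alternating) and room and
    target side are counterbalanced within blocks.  Trial order is shuffled
    independently per block from ``config.seed``.
    """
    tpb = config.trials_per_block
    if tpb % 2:
        raise ValueError("trials per block must be even to counterbalance")
    rng = np.random.default_rng(config.seed)
    rooms: tuple[Room, Room] = (
        ("anechoic", "reverberant") if config.first_room == "anechoic"
        else ("reverberant", "anechoic"))

    trials: list[TrialSpec] = []
    for block in range(config.n_blocks):
        if config.blocking_mode == "by_room":
            room = rooms[block % 2]
            cells = _counterbalanced_pairs([False, True], ["left", "right"],
                                           tpb)
            block_trials = [(room, interrupted, side)
                            for interrupted, side in cells]
        else:
            interrupted = bool(block % 2 == 0)
            cells = _counterbalanced_pairs(rooms, ["left", "right"], tpb)
            block_trials = [(room, interrupted, side)
                            for room, side in cells]
        order = rng.permutation(tpb)
        for i, j in enumerate(order):
            room, interrupted, side = block_trials[j]
            syllables = tuple(
                rng.choice(SYLLABLE_SET, size=config.syllables_per_stream,
                           replace=True))
            trials.append(TrialSpec(
                trial_index=block * tpb + i,
                block_index=block,
                room=room,
                interrupted=interrupted,
                target_side=side,
                target_leading=(side == config.leading_side),
                target_syllables=syllables,
            ))
    return trials


def build_schedule(trial: TrialSpec, config: DesignConfig) -> StimulusSchedule:
    """Event times for one trial, on the cue-onset clock (t = 0 at cue onset)."""
    cue_end = float(config.cue_duration)
    soa = config.syllable_duration + config.intersyllable_gap
    k = np.arange(config.syllables_per_stream)
    leading = cue_end + config.lead_onset_after_cue + k * soa
    lagging = leading + config.stream_lag
    if trial.target_leading:
        target, distractor = leading, lagging
    else:
        target, distractor = lagging, leading

    interrupter = None
    if trial.interrupted:
        interrupter = float(target[1]) - config.interrupter_lead
        if interrupter <= 0:
            raise ValueError("interrupter precedes recording window")
    return StimulusSchedule(
        cue_offset_time=cue_end,
        target_onsets=tuple(float(t) for t in target),
        distractor_onsets=tuple(float(t) for t in distractor),
        interrupter_onset=interrupter,
    )


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def design_frame(trials: Sequence[TrialSpec],
                 config: DesignConfig) -> pd.DataFrame:
    """One row per trial with condition labels and event onsets (seconds)."""
    rows = []
    for t in trials:
        sched = build_schedule(t, config)
        rows.append({
            "trial": t.trial_index,
            "block": t.block_index,
            "room": t.room,
            "interrupted": int(t.interrupted),
            "target_side": t.target_side,
            "target_leading": int(t.target_leading),
            "syllables": "-".join(t.target_syllables),
            "cue_offset_s": sched.cue_offset_time,
            "target_onsets_s": ";".join(f"{x:.6f}" for x in sched.target_onsets),
            "distractor_onsets_s": ";".join(
                f"{x:.6f}" for x in sched.distractor_onsets),
            "interrupter_onset_s": ("" if sched.interrupter_onset is None
                                    else f"{sched.interrupter_onset:.6f}"),
        })
    return pd.DataFrame(rows)


def design_from_frame(df: pd.DataFrame) -> list[TrialSpec]:
    """Rebuild TrialSpecs from a design table written by :func:`design_frame`."""
    trials = []
    for _, r in df.iterrows():
        trials.append(TrialSpec(
            trial_index=int(r["trial"]),
            block_index=int(r["block"]),
            room=str(r["room"]),
            interrupted=bool(int(r["interrupted"])),
            target_side=str(r["target_side"]),
            target_leading=bool(int(r["target_leading"])),
            target_syllables=tuple(str(r["syllables"]).split("-")),
        ))
    return trials
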