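"""End-to-end orchestration: simulate a cohort, preprocess, analyze, report.

All randomness flows from one root seed through named substreams; every
output directory carries a manifest with the config hash and seed so reruns
are reproducible and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import behavior_stats as bs
from . import peak_stats as ps
from . import pupil_preprocess as pp
from . import synthetic_data as sd
from . import timecourse_stats as ts
from .trial_design import DesignConfig, build_design, design_frame, design_from_frame

log = logging.getLogger("attnpupil")


@dataclass
class RunConfig:
    """Parameters for a full simulate/analyze run."""

    n_subjects: int = 10
    seed: int = 0
    # design
    design: DesignConfig = field(default_factory=DesignConfig)
    # generators
    pupil: sd.PupilGenParams = field(default_factory=sd.PupilGenParams)
    behavior: sd.BehaviorGenParams = field(default_factory=sd.BehaviorGenParams)
    # preprocessing
    pre_pad: float = 0.050
    post_pad: float = 0.150
    filter_order: int = 4
    filter_cutoff: float = 10.0
    epoch_window: tuple[float, float] = (-1.0, 7.0)
    baseline_window: tuple[float, float] = (-0.5, 0.0)
    exclusion_threshold: float = 0.5
    phasic_mode: pp.PhasicMode = "zscore"
    # statistics
    n_permutations: int = 10_000
    alpha: float = 0.05
    cluster_null_mode: ts.NullMode = "max"
    peak_search_window: tuple[float, float] = (0.0, 7.0)
    peak_half_width: float = 0.050

    @classmethod
    def from_json(cls, path: Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        for key, sub in (("design", DesignConfig),
                         ("pupil", sd.PupilGenParams),
                         ("behavior", sd.BehaviorGenParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**{
                    k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in raw[key].items()})
        for key in ("epoch_window", "baseline_window", "peak_search_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pupil"]["amplitudes"] = dict(d["pupil"]["amplitudes"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def substream_seed(root: int, *keys: int) -> int:
    """Deterministic child seed for a named substream of the root seed."""
    ss = np.random.SeedSequence([root, *keys])
    return int(ss.generate_state(1)[0])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def run_simulate(config: RunConfig, outdir: Path) -> dict:
    """Write per-subject design, sample, event and response files.

    Returns the manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}
    if config.n_subjects == 0:
        warnings.warn("n_subjects = 0: writing an empty manifest", stacklevel=2)
    responses = []
    for subj in range(config.n_subjects):
        dcfg = dataclasses.replace(
            config.design, seed=substream_seed(config.seed, subj, 0))
        design = build_design(dcfg)
        dframe = design_frame(design, dcfg)
        series, events = sd.simulate_subject(
            design, dcfg, config.pupil,
            seed=substream_seed(config.seed, subj, 1))
        resp = sd.simulate_behavior(
            design, config.behavior, subject=subj,
            seed=substream_seed(config.seed, subj, 2))
        responses.append(resp)
        prefix = f"sub-{subj:02d}"
        dframe.to_csv(outdir / f"{prefix}_design.csv", index=False)
        series.to_frame().to_csv(outdir / f"{prefix}_samples.csv", index=False,
                                 float_format="%.6f")
        events.to_csv(outdir / f"{prefix}_events.csv", index=False)
        files[prefix] = {
            "design": f"{prefix}_design.csv",
            "samples": f"{prefix}_samples.csv",
            "events": f"{prefix}_events.csv",
        }
        log.info("simulated subject %d (%d trials)", subj, len(design))
    if responses:
        pd.concat(responses, ignore_index=True).to_csv(
            outdir / "responses.csv", index=False)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "subjects": files,
        "responses": "responses.csv" if responses else None,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=list))
    return manifest


# ---------------------------------------------------------------------------
# Per-subject preprocessing
# ---------------------------------------------------------------------------

@dataclass
class SubjectResult:
    subject: int
    missing_fraction: float
    baseline: pp.BaselineStats
    epochs: pp.EpochSet
    phasic_by_cell: dict[tuple[str, int], pp.PhasicTrace]
    tonic_by_room: dict[str, float]


def preprocess_subject(subject: int, series: pp.SampleSeries,
                       events: pd.DataFrame, config: RunConfig) -> SubjectResult:
    """Interpolate, filter, epoch, and baseline one subject's recording."""
    missing = series.missing_fraction
    raw_valid = series.valid.copy()
    clean = pp.interpolate_blinks(series, config.pre_pad, config.post_pad)
    filtered = pp.lowpass(clean, config.filter_order, config.filter_cutoff)
    epochs = pp.epoch(filtered, events["cue_onset_s"].to_numpy(),
                      config.epoch_window,
                      trial_labels=events[["room", "interrupted"]],
                      raw_valid=raw_valid)
    baseline = pp.baseline_stats(epochs, config.baseline_window)

    phasic_by_cell = {}
    labels = epochs.trial_labels
    for room in ("anechoic", "reverberant"):
        for interrupted in (0, 1):
            mask = ((labels["room"] == room)
                    & (labels["interrupted"] == interrupted)).to_numpy()
            if mask.any():
                phasic_by_cell[(room, interrupted)] = pp.phasic(
                    epochs, baseline, config.phasic_mode, mask)
    tonic_by_room = {
        room: float(baseline.per_trial_baseline[
            (labels["room"] == room).to_numpy()].mean())
        for room in ("anechoic", "reverberant")
        if (labels["room"] == room).any()}
    return SubjectResult(subject=subject, missing_fraction=missing,
                         baseline=baseline, epochs=epochs,
                         phasic_by_cell=phasic_by_cell,
                         tonic_by_room=tonic_by_room)


# ---------------------------------------------------------------------------
# Cohort analysis
# ---------------------------------------------------------------------------

def _load_subject(outdir: Path, prefix: str) -> tuple[pp.SampleSeries, pd.DataFrame]:
    samples = pd.read_csv(outdir / f"{prefix}_samples.csv")
    events = pd.read_csv(outdir / f"{prefix}_events.csv")
    return pp.SampleSeries.from_frame(samples), events


def run_analyze(indir: Path, outdir: Path, config: RunConfig) -> dict:
    """Full analysis of a simulated (or equivalently formatted) data bundle."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((indir / "manifest.json").read_text())
    subjects = sorted(manifest["subjects"])

    results: list[SubjectResult] = []
    missing_by_subject: dict[int, float] = {}
    for prefix in subjects:
        subj = int(prefix.split("-")[1])
        series, events = _load_subject(indir, prefix)
        try:
            res = preprocess_subject(subj, series, events, config)
        except Exception as exc:  # surface stage + subject
            raise RuntimeError(
                f"preprocess failed for subject {subj}: {exc}") from exc
        missing_by_subject[subj] = res.missing_fraction
        results.append(res)

    retained, qc = pp.exclude_high_missing(missing_by_subject,
                                           config.exclusion_threshold)
    qc.to_csv(outdir / "qc.csv", index=False)
    (outdir / "qc.json").write_text(qc.to_json(orient="records", indent=2))
    results = [r for r in results if r.subject in retained]
    if not results:
        raise RuntimeError("all subjects excluded by the missing-data rule")
    log.info("retained %d/%d subjects", len(results), len(subjects))

    # ---- behavior ----
    responses = pd.read_csv(indir / "responses.csv")
    responses = responses[responses["subject"].isin(retained)]
    design_by_subject = {
        int(prefix.split("-")[1]): pd.read_csv(indir / f"{prefix}_design.csv")
        for prefix in subjects}
    scored_parts = []
    for subj, group in responses.groupby("subject"):
        scored = bs.score_responses(group)
        scored_parts.append(scored.merge(
            design_by_subject[int(subj)][["trial", "room", "interrupted"]],
            on="trial", how="left"))
    scored_all = pd.concat(scored_parts, ignore_index=True)
    grouped = scored_all.groupby(
        ["subject", "room", "interrupted", "position"], observed=True)
    acc = grouped["correct"].agg(accuracy="mean", n_trials="size").reset_index()
    acc.to_csv(outdir / "accuracy.csv", index=False)
    anova = bs.rm_anova(acc)
    anova.to_csv(outdir / "anova.csv", index=False)
    effect = bs.interruption_effect(acc)
    effect.to_csv(outdir / "interruption_effect.csv", index=False)
    eff_pos = effect.groupby(["subject", "position"])["effect"].mean().reset_index()
    eff_pos["condition"] = "pos" + eff_pos["position"].astype(str)
    positions = sorted(eff_pos["position"].unique())
    comparisons = [(f"pos{a}", f"pos{b}")
                   for i, a in enumerate(positions) for b in positions[i + 1:]]
    posthoc = bs.posthoc_paired(eff_pos, comparisons, value="effect",
                                alpha=config.alpha)
    posthoc.to_csv(outdir / "posthoc.csv", index=False)

    # ---- phasic time-course tests: interrupted vs uninterrupted per room ----
    epoch_time = results[0].phasic_by_cell[("anechoic", 0)].epoch_time
    trace_rows = []
    cluster_tables = {}
    for room in ("anechoic", "reverberant"):
        a = np.array([r.phasic_by_cell[(room, 1)].trace for r in results])
        b = np.array([r.phasic_by_cell[(room, 0)].trace for r in results])
        traces = ts.PairedTraceSet(a, b, epoch_time)
        res = ts.cluster_permutation_test(
            traces, n_permutations=config.n_permutations, alpha=config.alpha,
            null_mode=config.cluster_null_mode,
            seed=substream_seed(config.seed, 10, 0 if room == "anechoic" else 1))
        rows = [{"start_s": c.start_time, "end_s": c.end_time,
                 "t_sum": c.t_sum, "p": c.p_value,
                 "significant": c.significant} for c in res.clusters]
        tbl = pd.DataFrame(rows, columns=["start_s", "end_s", "t_sum", "p",
                                          "significant"])
        tbl.to_csv(outdir / f"clusters_{room}.csv", index=False)
        cluster_tables[room] = tbl
    for r in results:
        for (room, interrupted), trace in r.phasic_by_cell.items():
            trace_rows.append(pd.DataFrame({
                "subject": r.subject, "room": room, "interrupted": interrupted,
                "time_s": trace.epoch_time, "value": trace.trace}))
    pd.concat(trace_rows, ignore_index=True).to_csv(
        outdir / "phasic_traces.csv", index=False, float_format="%.6f")

    # ---- peak measures and sign-flip effect tests ----
    peak_rows = []
    for r in results:
        for (room, interrupted), trace in r.phasic_by_cell.items():
            pm = ps.measure_peak(trace, config.peak_search_window,
                                 config.peak_half_width, subject=r.subject,
                                 condition=f"{room}_{interrupted}")
            peak_rows.append({"subject": r.subject, "room": room,
                              "interrupted": interrupted,
                              "latency_s": pm.latency,
                              "amplitude": pm.amplitude})
    peaks = pd.DataFrame(peak_rows)
    peaks.to_csv(outdir / "peaks.csv", index=False)

    effects = {}
    for measure in ("amplitude", "latency_s"):
        wide = peaks.pivot_table(index="subject",
                                 columns=["room", "interrupted"],
                                 values=measure)
        d_int = (wide[("anechoic", 1)] + wide[("reverberant", 1)]
                 - wide[("anechoic", 0)] - wide[("reverberant", 0)]) / 2
        d_env = (wide[("anechoic", 0)] + wide[("anechoic", 1)]
                 - wide[("reverberant", 0)] - wide[("reverberant", 1)]) / 2
        d_inter = ((wide[("anechoic", 1)] - wide[("anechoic", 0)])
                   - (wide[("reverberant", 1)] - wide[("reverberant", 0)]))
        if len(d_int) >= 3:
            normality = ps.shapiro_wilk_gate(d_int.to_numpy())
        else:  # too few subjects for the gate; permutation path regardless
            normality = (float("nan"), float("nan"), False)
        tests = {}
        for name, scores, fn, key in (
                ("interruption", d_int, ps.signflip_mean_test, 20),
                ("environment", d_env, ps.signflip_mean_test, 21),
                ("interaction", d_inter, ps.interaction_signflip_test, 22)):
            et = fn(scores.to_numpy(), n_permutations=config.n_permutations,
                    seed=substream_seed(config.seed, key,
                                        0 if measure == "amplitude" else 1))
            tests[name] = {"observed": et.observed_effect,
                           "p": et.p_two_tailed,
                           "n_permutations": et.n_permutations,
                           "exhaustive": et.exhaustive}
        effects[measure] = {
            "shapiro": {"W": normality[0], "p": normality[1],
                        "use_parametric": normality[2]},
            "tests": tests}

    # ---- tonic comparison across rooms ----
    tonic = pd.DataFrame([
        {"subject": r.subject, **r.tonic_by_room} for r in results])
    t_stat, t_p = sps.ttest_rel(tonic["anechoic"], tonic["reverberant"])
    effects["tonic_room_ttest"] = {"t": float(t_stat), "p": float(t_p),
                                   "df": len(tonic) - 1}

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects_retained": len(results),
        "excluded_subjects": sorted(set(missing_by_subject) - set(retained)),
        "effects": effects,
        "clusters": {room: tbl.to_dict(orient="records")
                     for room, tbl in cluster_tables.items()},
    }
    (outdir / "effects.json").write_text(json.dumps(summary, indent=2))
    return summary
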