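"""Serial-recall scoring, accuracy tables, interruption effect, and RM-ANOVA.

Scoring is strict positional matching.  The ANOVA is a fully within-subject
(repeated-measures) decomposition on per-subject cell means: each effect is
tested against its interaction with the subject blocking factor, with
uncorrected degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FACTORS = ("room", "interrupted", "position")


def score_recall(targets: Sequence[str], response: Sequence[str]) -> np.ndarray:
    """Positional scoring: position i is correct iff response[i] == targets[i]."""
    if len(targets) != len(response):
        raise ValueError(
            f"length mismatch: {len(targets)} targets vs {len(response)} responses")
    return np.array([r == t for t, r in zip(targets, response)], dtype=bool)


def score_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Add a ``correct`` column to a long-format response table.

    Expects columns ``subject, trial, position, target, response``.  Rows with
    missing target or response are rejected.
    """
    required = {"subject", "trial", "position", "target", "response"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    bad = responses["target"].isna() | responses["response"].isna()
    if bad.any():
        raise ValueError(f"{int(bad.sum())} malformed response rows")
    out = responses.copy()
    out["correct"] = (out["target"] == out["response"]).astype(int)
    return out


def accuracy_table(scored: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per subject x room x interruption x position.

    ``scored`` carries subject/trial/position/correct; ``design`` maps trial
    to room and interrupted.  Returns a long table with columns
    ``subject, room, interrupted, position, accuracy, n_trials``.
    """
    labels = design[["trial", "room", "interrupted"]]
    merged = scored.merge(labels, on="trial", how="left", validate="m:1")
    if merged["room"].isna().any():
        bad = merged.loc[merged["room"].isna(), "trial"].unique()
        raise ValueError(f"trials missing from design: {bad.tolist()}")
    grouped = merged.groupby(["subject", "room", "interrupted", "position"],
                             observed=True)
    table = grouped["correct"].agg(accuracy="mean", n_trials="size").reset_index()
    # a complete design populates every cell for every subject
    n_cells = (table.groupby("subject", observed=True).size())
    expected = table["room"].nunique() * table["interrupted"].nunique() \
        * table["position"].nunique()
    short = n_cells[n_cells < expected]
    if len(short):
        raise ValueError(
            f"empty design cells for subjects {short.index.tolist()}")
    return table


def interruption_effect(table: pd.DataFrame) -> pd.DataFrame:
    """Uninterrupted-minus-interrupted accuracy per subject x room x position."""
    levels = set(table["interrupted"].unique())
    if levels != {0, 1}:
        raise ValueError(f"need both interruption levels, found {sorted(levels)}")
    wide = table.pivot_table(index=["subject", "room", "position"],
                             columns="interrupted", values="accuracy")
    out = wide.reset_index()
    out["effect"] = out[0] - out[1]
    return out[["subject", "room", "position", "effect"]]


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float


def _subsets(items: Sequence[str]):
    return chain.from_iterable(combinations(items, r)
                               for r in range(1, len(items) + 1))


def rm_anova(table: pd.DataFrame, dv: str = "accuracy",
             within: Sequence[str] = FACTORS,
             subject: str = "subject") -> pd.DataFrame:
    """Fully within-subject ANOVA on a complete balanced long table.

    Every effect (each non-empty subset of the within factors) is tested
    against its interaction with the subject factor.  No sphericity
    correction is applied; plain degrees of freedom are reported.
    """
    factors = list(within)
    levels = {f: sorted(table[f].unique()) for f in factors}
    n_subj = table[subject].nunique()
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    shape = [n_subj] + [len(levels[f]) for f in factors]
    expected = int(np.prod(shape))
    if len(table) != expected:
        raise ValueError(
            f"incomplete design: {len(table)} rows, expected {expected}")

    idx = {subject: {s: i for i, s in
                     enumerate(sorted(table[subject].unique()))}}
    for f in factors:
        idx[f] = {lv: i for i, lv in enumerate(levels[f])}
    y = np.full(shape, np.nan)
    subs = table[subject].map(idx[subject]).to_numpy()
    coords = [subs] + [table[f].map(idx[f]).to_numpy() for f in factors]
    y[tuple(coords)] = table[dv].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("incomplete design: empty cells")

    all_names = [subject] + factors
    axis_of = {name: i for i, name in enumerate(all_names)}
    n_total = y.size
    grand = y.sum()

    def t_term(names: tuple[str, ...]) -> float:
        """Sum over kept cells of (cell total)^2 / cells collapsed."""
        if not names:
            return grand**2 / n_total
        keep = tuple(axis_of[nm] for nm in names)
        drop = tuple(i for i in range(len(all_names)) if i not in keep)
        totals = y.sum(axis=drop)
        n_per = n_total / totals.size
        return float((totals**2).sum() / n_per)

    def ss(names: tuple[str, ...]) -> float:
        total = 0.0
        for r in range(len(names) + 1):
            for sub in combinations(names, r):
                total += (-1) ** (len(names) - len(sub)) * t_term(sub)
        return total

    rows = []
    for effect in _subsets(factors):
        df_num = int(np.prod([len(levels[f]) - 1 for f in effect]))
        df_den = df_num * (n_subj - 1)
        ss_eff = ss(tuple(effect))
        ss_err = ss(tuple(effect) + (subject,))
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        F = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(stats.f.sf(F, df_num, df_den))
        rows.append({"effect": " x ".join(effect), "SS": ss_eff,
                     "SS_error": ss_err, "df_num": df_num, "df_den": df_den,
                     "F": float(F), "p": p})
    return pd.DataFrame(rows)


def posthoc_paired(data: pd.DataFrame, comparisons: Sequence[tuple],
                   value: str = "accuracy", unit: str = "subject",
                   condition: str = "condition", alpha: float = 0.05
                   ) -> pd.DataFrame:
    """Paired t-tests with Bonferroni correction.

    ``comparisons`` is a sequence of (level_a, level_b) pairs of the
    ``condition`` column; observations are paired by ``unit``.  The adjusted
    p is ``min(1, m * p)`` over the m requested comparisons.
    """
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        wide = data[data[condition].isin([a, b])].pivot_table(
            index=unit, columns=condition, values=value)
        if wide[[a, b]].dropna().shape[0] < 2:
            raise ValueError(f"comparison {a!r} vs {b!r}: fewer than 2 pairs")
        paired = wide[[a, b]].dropna()
        diff = (paired[a] - paired[b]).to_numpy()
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(paired[a], paired[b])
        p_adj = min(1.0, m * float(p))
        rows.append({"level_a": a, "level_b": b,
                     "mean_diff": float((paired[a] - paired[b]).mean()),
                     "t": float(t), "df": len(paired) - 1, "p_raw": float(p),
                     "p_bonferroni": p_adj,
                     "significant": p_adj < alpha})
    return pd.DataFrame(rows)
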