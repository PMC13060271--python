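"""Paired cluster-based permutation testing on time courses.

Clusters are maximal contiguous runs of time points whose pointwise paired
t-value exceeds a two-sided threshold with constant sign; the cluster
statistic is the sum of t-values in the run (T-sum).  The null distribution
is built by sign-flipping each subject's whole difference waveform and, by
default, taking the maximum |T-sum| per permutation (family-wise control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats

NullMode = Literal["max", "pooled"]


@dataclass
class PairedTraceSet:
    """Aligned per-subject traces for two conditions on a common time grid."""

    condition_a: np.ndarray       # subjects x time
    condition_b: np.ndarray       # subjects x time
    epoch_time: np.ndarray

    def __post_init__(self) -> None:
        self.condition_a = np.atleast_2d(np.asarray(self.condition_a, float))
        self.condition_b = np.atleast_2d(np.asarray(self.condition_b, float))
        self.epoch_time = np.asarray(self.epoch_time, float)
        if self.condition_a.shape != self.condition_b.shape:
            raise ValueError("condition arrays must have identical shape")
        if self.condition_a.shape[1] != self.epoch_time.size:
            raise ValueError("trace length must match epoch_time")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")

    @property
    def n_subjects(self) -> int:
        return self.condition_a.shape[0]

    @property
    def differences(self) -> np.ndarray:
        return self.condition_a - self.condition_b


@dataclass
class Cluster:
    start_index: int
    end_index: int               # half-open
    start_time: float
    end_time: float
    t_sum: float
    p_value: Optional[float] = None
    significant: Optional[bool] = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    pointwise_t: np.ndarray
    threshold_t: float
    null_distribution: np.ndarray
    null_mode: NullMode
    n_permutations: int
    exhaustive: bool
    seed: Optional[int]

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Pointwise paired t over axis 0 with df = n-1; zero-variance points -> 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    if not nz.all() and np.any(mean[~nz] != 0):
        warnings.warn("zero-variance time points with nonzero mean: t set to 0",
                      stacklevel=2)
    return t


def pointwise_paired_t(traces: PairedTraceSet) -> np.ndarray:
    """Paired t-value at each time point (condition A minus B)."""
    return _paired_t(traces.differences)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def form_clusters(t_trace: np.ndarray, n_subjects: int,
                  epoch_time: Optional[np.ndarray] = None,
                  alpha_cluster: float = 0.05) -> tuple[list[Cluster], float]:
    """Maximal sign-constant supra-threshold runs with their T-sums.

    The threshold is the two-sided critical t at df = n-1.  Positive and
    negative excursions form separate clusters, so a sign change inside a
    supra-|t| run splits it.  Clusters touching the trace edge are retained.
    """
    threshold = float(stats.t.ppf(1 - alpha_cluster / 2, n_subjects - 1))
    if epoch_time is None:
        epoch_time = np.arange(t_trace.size, dtype=float)
    clusters = []
    for sign in (1.0, -1.0):
        for a, b in _runs(sign * t_trace > threshold):
            clusters.append(Cluster(
                start_index=a, end_index=b,
                start_time=float(epoch_time[a]),
                end_time=float(epoch_time[b - 1]),
                t_sum=float(t_trace[a:b].sum())))
    clusters.sort(key=lambda c: c.start_index)
    return clusters, threshold


def _cluster_stats_matrix(t_mat: np.ndarray, threshold: float,
                          mode: NullMode) -> np.ndarray | list[np.ndarray]:
    """Per-row cluster statistics of a (permutations x time) t matrix.

    ``mode='max'``: the maximum |T-sum| per row (0 when a row has no
    clusters).  ``mode='pooled'``: all |T-sum| values pooled across rows.
    Vectorized: positive and negative excursions are scanned on the
    flattened matrix with a sentinel column so runs never span rows.
    """
    P, T = t_mat.shape
    row_stat = np.zeros(P)
    pooled: list[np.ndarray] = []
    sentinel = np.zeros((P, 1), dtype=bool)
    for sign in (1.0, -1.0):
        mask = np.concatenate([sign * t_mat > threshold, sentinel], axis=1)
        flat = mask.ravel()
        edges = np.flatnonzero(np.diff(
            np.concatenate([[False], flat]).astype(np.int8)))
        if edges.size == 0:
            continue
        starts, ends = edges[::2], edges[1::2]
        flat_t = np.concatenate([sign * t_mat, np.zeros((P, 1))], axis=1).ravel()
        csum = np.concatenate([[0.0], np.cumsum(flat_t)])
        sums = csum[ends] - csum[starts]          # positive by construction
        rows = starts // (T + 1)
        if mode == "max":
            np.maximum.at(row_stat, rows, sums)
        else:
            pooled.append(sums)
    if mode == "max":
        return row_stat
    return np.concatenate(pooled) if pooled else np.array([])


def _sign_matrix(n: int, n_permutations: int, exhaustive: bool,
                 rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    if exhaustive:
        codes = np.arange(2**n, dtype=np.int64)
        bits = (codes[:, None] >> np.arange(n)) & 1
        return 2.0 * bits - 1.0, True
    return rng.choice([-1.0, 1.0], size=(n_permutations, n)), False


def cluster_permutation_test(
    traces: PairedTraceSet,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    alpha_cluster: float = 0.05,
    null_mode: NullMode = "max",
    exhaustive: Optional[bool] = None,
    seed: Optional[int] = None,
) -> ClusterResult:
    """Paired cluster-based sign-flip permutation test.

    For each permutation every subject's whole difference waveform is
    multiplied by a random sign; the permutation's cluster statistic (max
    |T-sum| by default) enters the null distribution.  An observed cluster is
    significant when its |T-sum| exceeds the null's ``1 - alpha`` quantile;
    per-cluster p-values use the inclusive rule (proportion of null values
    >= |T-sum|), so p is never exactly 0.  When ``exhaustive`` (default for
    n <= 12) all 2^n sign patterns are enumerated.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: p-values will be coarse",
                      stacklevel=2)
    diffs = traces.differences
    n = traces.n_subjects
    if exhaustive is None:
        exhaustive = n <= 12

    t_obs = _paired_t(diffs)
    clusters, threshold = form_clusters(t_obs, n, traces.epoch_time,
                                        alpha_cluster)

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_permutations, exhaustive, rng)

    # permuted t traces in blocks to bound memory
    n_time = diffs.shape[1]
    null_parts = []
    block = max(1, int(5e6 // max(n_time, 1)))
    sq = diffs**2
    for lo in range(0, signs.shape[0], block):
        s = signs[lo:lo + block]
        mean = s @ diffs / n
        # sign flips leave squares unchanged, so E[x^2] term is fixed
        var = (sq.sum(axis=0) - n * mean**2) / (n - 1)
        sd = np.sqrt(np.maximum(var, 0))
        t_mat = np.zeros_like(mean)
        nz = sd > 0
        np.divide(mean, sd / np.sqrt(n), out=t_mat, where=nz)
        null_parts.append(_cluster_stats_matrix(t_mat, threshold, null_mode))
    null = np.concatenate(null_parts) if null_parts else np.array([])
    if null_mode == "pooled" and null.size == 0:
        null = np.zeros(1)

    cutoff = float(np.quantile(null, 1 - alpha)) if null.size else np.inf
    for c in clusters:
        # relative tolerance keeps the inclusive rule exact for the identity
        # permutation despite float round-off in the vectorized null
        tol = 1e-9 * max(1.0, abs(c.t_sum))
        c.p_value = (float(np.mean(null >= abs(c.t_sum) - tol))
                     if null.size else 1.0)
        c.significant = abs(c.t_sum) > cutoff

    return ClusterResult(
        clusters=clusters, pointwise_t=t_obs, threshold_t=threshold,
        null_distribution=null, null_mode=null_mode,
        n_permutations=int(signs.shape[0]), exhaustive=bool(exhaustive),
        seed=seed)
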