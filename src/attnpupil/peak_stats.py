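"""Peak latency/amplitude extraction and scalar sign-flip permutation tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .pupil_preprocess import PhasicTrace


@dataclass(frozen=True)
class PeakMeasure:
    latency: float
    amplitude: float
    subject: Optional[int] = None
    condition: Optional[str] = None


@dataclass(frozen=True)
class EffectTest:
    """Result of a sign-flip permutation test on subject-level differences."""

    observed_effect: float
    p_two_tailed: float
    null_mean: float
    null_sd: float
    n_permutations: int
    exhaustive: bool
    seed: Optional[int]


def peak_latency(trace: PhasicTrace,
                 search_window: tuple[float, float] = (0.0, 7.0)) -> float:
    """Time of the maximum trace value within the window; earliest tie wins."""
    t = trace.epoch_time
    sel = (t >= search_window[0]) & (t <= search_window[1])
    if not sel.any():
        raise ValueError("search window contains no samples")
    vals = trace.trace[sel]
    times = t[sel]
    return float(times[int(np.argmax(vals))])


def peak_amplitude(trace: PhasicTrace, latency: float,
                   half_width: float = 0.050) -> float:
    """Mean trace value over |t - latency| <= half_width, truncated at edges."""
    sel = np.abs(trace.epoch_time - latency) <= half_width + 1e-12
    if not sel.any():
        raise ValueError("amplitude window does not intersect the trace")
    return float(trace.trace[sel].mean())


def measure_peak(trace: PhasicTrace,
                 search_window: tuple[float, float] = (0.0, 7.0),
                 half_width: float = 0.050,
                 subject: Optional[int] = None,
                 condition: Optional[str] = None) -> PeakMeasure:
    lat = peak_latency(trace, search_window)
    amp = peak_amplitude(trace, lat, half_width)
    return PeakMeasure(latency=lat, amplitude=amp, subject=subject,
                       condition=condition)


def shapiro_wilk_gate(values: Sequence[float],
                      alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality check used as a reported gate.

    Returns (W, p, use_parametric).  The inferential path downstream is
    always the permutation tests; the gate only documents whether a
    parametric alternative would have been defensible.  Degenerate
    (zero-variance) samples force the nonparametric path with W = p = nan.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if values.size > 5000:
        raise ValueError("Shapiro-Wilk approximation invalid beyond n = 5000")
    if np.ptp(values) == 0:
        warnings.warn("constant sample: normality undefined, "
                      "forcing nonparametric path", stacklevel=2)
        return float("nan"), float("nan"), False
    W, p = stats.shapiro(values)
    return float(W), float(p), bool(p >= alpha)


def _null_means(diffs: np.ndarray, n_permutations: int,
                exhaustive: Optional[bool],
                rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    n = diffs.size
    if exhaustive is None:
        exhaustive = n <= 16
    if exhaustive:
        codes = np.arange(2**n, dtype=np.int64)
        signs = ((codes[:, None] >> np.arange(n)) & 1) * 2.0 - 1.0
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    return signs @ diffs / n, bool(exhaustive)


def signflip_mean_test(differences: Sequence[float],
                       n_permutations: int = 10_000,
                       seed: Optional[int] = None,
                       exhaustive: Optional[bool] = None) -> EffectTest:
    """Two-tailed sign-flip permutation test of a zero-mean null.

    The observed statistic is the mean difference; the null is the
    distribution of means under random per-subject sign flips.  p is the
    inclusive proportion of null means with |mean| >= |observed|; for
    n <= 16 all 2^n sign patterns are enumerated.
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least 2 difference scores")
    observed = float(diffs.mean())
    if np.all(diffs == 0):
        return EffectTest(observed_effect=0.0, p_two_tailed=1.0,
                          null_mean=0.0, null_sd=0.0,
                          n_permutations=0, exhaustive=True, seed=seed)
    rng = np.random.default_rng(seed)
    null, exh = _null_means(diffs, n_permutations, exhaustive, rng)
    p = float(np.mean(np.abs(null) >= abs(observed) - 1e-12))
    return EffectTest(observed_effect=observed, p_two_tailed=p,
                      null_mean=float(null.mean()), null_sd=float(null.std()),
                      n_permutations=int(null.size), exhaustive=exh, seed=seed)


def interaction_signflip_test(diff_of_diffs: Sequence[float],
                              n_permutations: int = 10_000,
                              seed: Optional[int] = None,
                              exhaustive: Optional[bool] = None) -> EffectTest:
    """Sign-flip test applied to per-subject difference-of-differences."""
    return signflip_mean_test(diff_of_diffs, n_permutations=n_permutations,
                              seed=seed, exhaustive=exhaustive)
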