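"""Room-acoustics utilities: sweep deconvolution, Schroeder RT60, windowing.

Impulse responses are recovered from sweep recordings by regularized
spectral division; reverberation time comes from a straight-line fit to the
Schroeder backward-integrated energy decay curve, extrapolated to -60 dB;
pseudo-anechoic responses are obtained by truncating after the direct path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np


@dataclass
class ImpulseResponse:
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("impulse response contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class AcousticResult:
    rt60: float
    decay_fit_range: tuple[float, float]   # dB
    fit_r_squared: float

    def __post_init__(self) -> None:
        if self.rt60 <= 0:
            raise ValueError("rt60 must be > 0")


def deconvolve_sweep(recording: np.ndarray, sweep: np.ndarray,
                     sampling_rate: float,
                     regularization: Optional[float] = None) -> ImpulseResponse:
    """Recover an impulse response by regularized spectral division.

    ``H = conj(S) * R / (|S|^2 + eps)`` where S and R are the spectra of the
    sweep and the recording; eps (Tikhonov) defaults to 1e-8 times the peak
    spectral power of the sweep.
    """
    recording = np.asarray(recording, dtype=float)
    sweep = np.asarray(sweep, dtype=float)
    if not np.any(sweep):
        raise ValueError("sweep signal is identically zero")
    n = recording.size + sweep.size - 1
    nfft = int(2 ** np.ceil(np.log2(n)))
    S = np.fft.rfft(sweep, nfft)
    R = np.fft.rfft(recording, nfft)
    power = np.abs(S) ** 2
    eps = regularization if regularization is not None else 1e-8 * power.max()
    h = np.fft.irfft(np.conj(S) * R / (power + eps), nfft)
    return ImpulseResponse(samples=h[:recording.size],
                           sampling_rate=sampling_rate)


def schroeder_decay(ir: ImpulseResponse) -> np.ndarray:
    """Backward-integrated energy decay curve in dB, 0 dB at t = 0."""
    energy = ir.samples**2
    total = energy.sum()
    if total <= 0:
        raise ValueError("impulse response has no energy")
    tail = np.cumsum(energy[::-1])[::-1]
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(tail / total)


def schroeder_rt60(ir: ImpulseResponse,
                   fit_range: tuple[float, float] = (-5.0, -25.0)
                   ) -> AcousticResult:
    """RT60 from a line fit to the Schroeder decay over ``fit_range`` dB.

    The fitted slope is extrapolated to -60 dB.  With the default (-5, -25)
    range this is a T20-style estimate (x3 extrapolation).
    """
    hi, lo = max(fit_range), min(fit_range)
    edc = schroeder_decay(ir)
    sel = (edc <= hi) & (edc >= lo)
    if sel.sum() < 10:
        raise ValueError(
            f"insufficient decay: curve does not span [{lo}, {hi}] dB")
    t = np.arange(ir.samples.size) / ir.sampling_rate
    slope, intercept = np.polyfit(t[sel], edc[sel], 1)
    if slope >= 0:
        raise ValueError("insufficient decay: non-decreasing energy curve")
    fitted = slope * t[sel] + intercept
    ss_res = float(((edc[sel] - fitted) ** 2).sum())
    ss_tot = float(((edc[sel] - edc[sel].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AcousticResult(rt60=float(-60.0 / slope),
                          decay_fit_range=(hi, lo), fit_r_squared=r2)


def window_direct_path(ir: ImpulseResponse, window_length: float,
                       taper: Literal["cosine", "rect"] = "cosine",
                       taper_fraction: float = 0.25,
                       onset_threshold: float = 0.1) -> ImpulseResponse:
    """Truncate an impulse response to its direct-path portion.

    The direct-path onset is the first sample whose magnitude reaches
    ``onset_threshold`` times the absolute peak; the response is zeroed
    ``window_length`` seconds after that onset, with an optional
    raised-cosine taper over the trailing ``taper_fraction`` of the window.
    """
    n = ir.samples.size
    win = int(round(window_length * ir.sampling_rate))
    if win <= 0:
        raise ValueError("window_length must be positive")
    peak = np.abs(ir.samples).max()
    if peak == 0:
        raise ValueError("impulse response is silent")
    onset = int(np.argmax(np.abs(ir.samples) >= onset_threshold * peak))
    if onset + win > n:
        raise ValueError("direct-path window extends past the response")
    out = ir.samples.copy()
    gate = np.zeros(n)
    gate[: onset + win] = 1.0
    if taper == "cosine":
        n_taper = max(1, int(round(taper_fraction * win)))
        ramp = 0.5 * (1 + np.cos(np.linspace(0, np.pi, n_taper)))
        gate[onset + win - n_taper: onset + win] = ramp
    return ImpulseResponse(samples=out * gate, sampling_rate=ir.sampling_rate)
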