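"""Frequency-domain COP measures from Welch power spectral density estimates.

Three spectral summaries are computed inside a fixed analysis band:

* mean frequency — the power-weighted average frequency,
* peak frequency — the frequency of maximal power (ties go to the lowest
  frequency),
* peak power — the maximal PSD value itself (mm^2/Hz), an index of the
  intensity of the dominant sway oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ParameterError, SwayError

__all__ = [
    "PSDSettings",
    "PSDEstimate",
    "estimate_psd",
    "mean_frequency",
    "peak_frequency",
    "peak_power",
]


@dataclass(frozen=True)
class PSDSettings:
    """Welch estimator settings.

    Defaults give 0.1 Hz resolution on a 30-s trial: 10-s Hann segments
    with 50% overlap, one-sided density scaling, constant detrend. The
    analysis band [0.05, 5] Hz excludes the DC bin and the filtered-out
    high band.
    """

    segment_s: float = 10.0
    overlap: float = 0.5
    window: str = "hann"
    band: tuple[float, float] = (0.05, 5.0)

    def __post_init__(self) -> None:
        if not self.segment_s > 0:
            raise ParameterError("segment_s must be positive")
        if not 0.0 <= self.overlap < 1.0:
            raise ParameterError("overlap must lie in [0, 1)")
        lo, hi = self.band
        if not 0 <= lo < hi:
            raise ParameterError(f"invalid analysis band {self.band}")


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided PSD on a frequency grid, with its analysis band."""

    freqs: np.ndarray
    power: np.ndarray
    band: tuple[float, float]
    settings: PSDSettings | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)
        if f.ndim != 1 or f.shape != p.shape:
            raise ParameterError("freqs and power must be 1-D arrays of equal length")
        if np.any(np.diff(f) <= 0):
            raise ParameterError("frequency grid must be strictly increasing")
        if np.any(p < 0):
            raise ParameterError("power values must be non-negative")

    def band_slice(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.band
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return self.freqs[m], self.power[m]


def estimate_psd(series: np.ndarray, fs: float, settings: PSDSettings = PSDSettings()) -> PSDEstimate:
    """Welch-averaged one-sided PSD of a displacement series.

    Density scaling is used, so the integral of power over frequency
    approximates the series variance (Parseval, within a few percent for
    broadband signals).

    Raises
    ------
    ParameterError
        If the configured segment is longer than the series.
    """
    x = np.asarray(series, dtype=float)
    nperseg = int(round(settings.segment_s * fs))
    if nperseg > x.size:
        raise ParameterError(
            f"segment of {nperseg} samples exceeds series length {x.size}"
        )
    freqs, power = signal.welch(
        x,
        fs=fs,
        window=settings.window,
        nperseg=nperseg,
        noverlap=int(round(settings.overlap * nperseg)),
        detrend="constant",
        scaling="density",
    )
    return PSDEstimate(freqs=freqs, power=power, band=settings.band, settings=settings)


def _band_or_raise(psd: PSDEstimate) -> tuple[np.ndarray, np.ndarray]:
    f, p = psd.band_slice()
    if f.size == 0 or not np.any(p > 0):
        raise SwayError("no power inside the analysis band; spectral measure undefined")
    return f, p


def mean_frequency(psd: PSDEstimate) -> float:
    """Power-weighted mean frequency over the analysis band (Hz)."""
    f, p = _band_or_raise(psd)
    if f.size < 2:
        raise SwayError("mean frequency needs at least 2 bins in the band")
    return float(np.trapezoid(f * p, f) / np.trapezoid(p, f))


def peak_frequency(psd: PSDEstimate) -> float:
    """Frequency of the maximal PSD value in the band; ties -> lowest frequency."""
    f, p = _band_or_raise(psd)
    return float(f[int(np.argmax(p))])


def peak_power(psd: PSDEstimate) -> float:
    """Maximal PSD value in the band (mm^2/Hz)."""
    _, p = _band_or_raise(psd)
    return float(np.max(p))
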