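"""Low-pass filtering and centring of COP trials.

Raw force-plate COP signals carry sensor noise above the band of postural
sway; the conventional treatment is a zero-phase Butterworth low-pass
filter followed by removal of each channel's mean, so that distances are
measured from the mean COP point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import COPTrial, ParameterError

__all__ = ["FilterSpec", "lowpass", "demean", "preprocess"]


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth low-pass filter parameters.

    Parameters
    ----------
    cutoff:
        Cutoff frequency in Hz; must lie below the Nyquist frequency of the
        trial it is applied to.
    order:
        Filter order (per pass; zero-phase application squares the
        magnitude response).
    zero_phase:
        Apply forward-backward (no time shift). A single forward pass is
        available for completeness but shifts the signal in time.
    """

    cutoff: float = 10.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")
        if self.order < 1:
            raise ParameterError(f"order must be >= 1, got {self.order}")


def _apply(x: np.ndarray, sos: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.zero_phase:
        # reflective padding long enough for the slowest pole's transient
        # to decay below double precision, so edges carry no filter state
        # and filtering commutes with time reversal
        r = float(np.max(np.abs(signal.sos2zpk(sos)[1])))
        decay = int(np.ceil(np.log(1e-12) / np.log(r))) if 0 < r < 1 else 0
        padlen = min(x.size - 1, max(3 * (2 * spec.order + 1), decay))
        return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)
    return signal.sosfilt(sos, x)


def lowpass(trial: COPTrial, spec: FilterSpec = FilterSpec()) -> COPTrial:
    """Low-pass filter both channels of a trial.

    Raises
    ------
    ParameterError
        If the cutoff is at or above the trial's Nyquist frequency.
    """
    nyquist = trial.fs / 2.0
    if spec.cutoff >= nyquist:
        raise ParameterError(
            f"cutoff {spec.cutoff} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz (fs={trial.fs} Hz)"
        )
    sos = signal.butter(spec.order, spec.cutoff, btype="lowpass", fs=trial.fs, output="sos")
    return trial.replace(
        ap=_apply(trial.ap, sos, spec, trial.fs),
        ml=_apply(trial.ml, sos, spec, trial.fs),
    )


def demean(trial: COPTrial) -> COPTrial:
    """Subtract each channel's mean, so the trajectory is centred on the mean COP."""
    return trial.replace(ap=trial.ap - trial.ap.mean(), ml=trial.ml - trial.ml.mean())


def preprocess(trial: COPTrial, spec: FilterSpec = FilterSpec()) -> COPTrial:
    """Standard preparation: low-pass filter, then centre on the mean COP."""
    return demean(lowpass(trial, spec))
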