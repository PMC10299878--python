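"""Stabilometric outcome measures from preprocessed COP trials.

Six measures are computed, most with overall/AP/ML components:

* mean distance (mm) — average deviation from the mean COP point
  (per axis: mean absolute value; overall: mean resultant distance),
* mean velocity (mm/s) — COP path length per unit time,
* sway area (mm^2) — area of the 95% prediction ellipse of the 2-D
  trajectory, ``pi * chi2_quantile(coverage, 2) * sqrt(det(cov))``,
* mean frequency, peak frequency, peak power — spectral summaries, see
  :mod:`swaylab.spectral`.

"Overall" time-domain measures use the 2-D resultant (Euclidean)
trajectory; "overall" spectral measures are computed on the resultant
distance series ``sqrt(ap^2 + ml^2)`` of the centred trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import COPTrial, ParameterError
from .preprocess import FilterSpec, preprocess
from .spectral import PSDSettings, estimate_psd, mean_frequency, peak_frequency, peak_power

__all__ = [
    "DirectionalValue",
    "StabilometricFeatures",
    "mean_distance",
    "mean_velocity",
    "sway_area",
    "spectral_features",
    "trial_features",
    "average_features",
    "subject_features",
    "cohort_features",
    "MEASURES",
]

log = logging.getLogger(__name__)

#: Canonical (measure, direction) rows, in reporting order.
MEASURES: tuple[tuple[str, str], ...] = (
    ("mean_velocity", "overall"),
    ("mean_velocity", "ap"),
    ("mean_velocity", "ml"),
    ("mean_distance", "overall"),
    ("mean_distance", "ap"),
    ("mean_distance", "ml"),
    ("mean_frequency", "overall"),
    ("mean_frequency", "ap"),
    ("mean_frequency", "ml"),
    ("peak_frequency", "overall"),
    ("peak_frequency", "ap"),
    ("peak_frequency", "ml"),
    ("peak_power", "overall"),
    ("peak_power", "ap"),
    ("peak_power", "ml"),
    ("sway_area", "none"),
)

_DEMEAN_TOL = 1e-6  # mm


@dataclass(frozen=True)
class DirectionalValue:
    """A measure's overall / AP / ML components."""

    overall: float
    ap: float
    ml: float


@dataclass(frozen=True)
class StabilometricFeatures:
    """The six outcome measures of one trial (or a trial average)."""

    mean_velocity: DirectionalValue
    mean_distance: DirectionalValue
    mean_frequency: DirectionalValue
    peak_frequency: DirectionalValue
    peak_power: DirectionalValue
    sway_area: float

    def to_series(self) -> pd.Series:
        """Tidy view indexed by (measure, direction)."""
        values = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, DirectionalValue):
                for d in ("overall", "ap", "ml"):
                    values[(f.name, d)] = getattr(v, d)
            else:
                values[(f.name, "none")] = v
        idx = pd.MultiIndex.from_tuples(MEASURES, names=["measure", "direction"])
        return pd.Series(values).reindex(idx)

    @classmethod
    def from_series(cls, s: pd.Series) -> "StabilometricFeatures":
        def dv(name: str) -> DirectionalValue:
            return DirectionalValue(
                overall=float(s[(name, "overall")]),
                ap=float(s[(name, "ap")]),
                ml=float(s[(name, "ml")]),
            )

        return cls(
            mean_velocity=dv("mean_velocity"),
            mean_distance=dv("mean_distance"),
            mean_frequency=dv("mean_frequency"),
            peak_frequency=dv("peak_frequency"),
            peak_power=dv("peak_power"),
            sway_area=float(s[("sway_area", "none")]),
        )


def _require_demeaned(trial: COPTrial) -> None:
    for name, x in (("ap", trial.ap), ("ml", trial.ml)):
        m = abs(float(x.mean()))
        if m > _DEMEAN_TOL:
            raise ParameterError(
                f"trial is not demeaned: |mean({name})| = {m:.3g} mm > {_DEMEAN_TOL} mm"
            )


def mean_distance(trial: COPTrial) -> DirectionalValue:
    """Mean distance from the mean COP point (mm); requires a demeaned trial."""
    _require_demeaned(trial)
    return DirectionalValue(
        overall=float(np.hypot(trial.ap, trial.ml).mean()),
        ap=float(np.abs(trial.ap).mean()),
        ml=float(np.abs(trial.ml).mean()),
    )


def mean_velocity(trial: COPTrial) -> DirectionalValue:
    """Path length per elapsed time (mm/s), with elapsed time (N-1)/fs."""
    dap = np.diff(trial.ap)
    dml = np.diff(trial.ml)
    elapsed = (trial.n_samples - 1) / trial.fs
    return DirectionalValue(
        overall=float(np.hypot(dap, dml).sum() / elapsed),
        ap=float(np.abs(dap).sum() / elapsed),
        ml=float(np.abs(dml).sum() / elapsed),
    )


def sway_area(trial: COPTrial, coverage: float = 0.95) -> float:
    """Area (mm^2) of the prediction ellipse covering ``coverage`` of a
    bivariate Gaussian with the trial's sample covariance.

    A degenerate covariance (all sway on one axis) yields area 0 with a
    logged warning.
    """
    if not 0.0 < coverage < 1.0:
        raise ParameterError(f"coverage must lie in (0, 1), got {coverage}")
    if trial.n_samples < 3:
        raise ParameterError("sway area needs at least 3 samples")
    _require_demeaned(trial)
    cov = np.cov(trial.ap, trial.ml, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 1e-12:
        log.warning("degenerate COP covariance (det=%.3g); sway area set to 0", det)
        return 0.0
    q = sps.chi2.ppf(coverage, df=2)
    return float(np.pi * q * np.sqrt(det))


def spectral_features(
    trial: COPTrial, settings: PSDSettings = PSDSettings()
) -> dict[str, DirectionalValue]:
    """Mean/peak frequency and peak power per direction.

    AP and ML use the respective channel; "overall" uses the resultant
    distance series of the centred trial.
    """
    _require_demeaned(trial)
    resultant = np.hypot(trial.ap, trial.ml)
    out: dict[str, dict[str, float]] = {k: {} for k in ("mean_frequency", "peak_frequency", "peak_power")}
    for direction, series in (("overall", resultant), ("ap", trial.ap), ("ml", trial.ml)):
        psd = estimate_psd(series, trial.fs, settings)
        out["mean_frequency"][direction] = mean_frequency(psd)
        out["peak_frequency"][direction] = peak_frequency(psd)
        out["peak_power"][direction] = peak_power(psd)
    return {k: DirectionalValue(**v) for k, v in out.items()}


def trial_features(
    trial: COPTrial,
    filter_spec: FilterSpec = FilterSpec(),
    psd_settings: PSDSettings = PSDSettings(),
    coverage: float = 0.95,
) -> StabilometricFeatures:
    """Full feature set of one raw trial: filter, centre, then measure."""
    prepared = preprocess(trial, filter_spec)
    spec = spectral_features(prepared, psd_settings)
    return StabilometricFeatures(
        mean_velocity=mean_velocity(prepared),
        mean_distance=mean_distance(prepared),
        mean_frequency=spec["mean_frequency"],
        peak_frequency=spec["peak_frequency"],
        peak_power=spec["peak_power"],
        sway_area=sway_area(prepared, coverage),
    )


def average_features(
    per_trial: list[StabilometricFeatures], require_three: bool = True
) -> StabilometricFeatures:
    """Element-wise arithmetic mean over a subject's trials.

    By default exactly three trials are required (the standard protocol);
    ``require_three=False`` relaxes this to at least one.
    """
    if require_three and len(per_trial) != 3:
        raise ParameterError(f"expected exactly 3 trials, got {len(per_trial)}")
    if not per_trial:
        raise ParameterError("no trials to average")
    stacked = pd.concat([f.to_series() for f in per_trial], axis=1)
    return StabilometricFeatures.from_series(stacked.mean(axis=1))


def subject_features(
    subject,
    filter_spec: FilterSpec = FilterSpec(),
    psd_settings: PSDSettings = PSDSettings(),
    coverage: float = 0.95,
) -> StabilometricFeatures:
    """Three-trial averaged features of one :class:`~swaylab.core.SubjectRecord`."""
    per_trial = [
        trial_features(t, filter_spec, psd_settings, coverage) for t in subject.trials
    ]
    return average_features(per_trial)


def cohort_features(
    cohort,
    filter_spec: FilterSpec = FilterSpec(),
    psd_settings: PSDSettings = PSDSettings(),
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Tidy per-subject feature table.

    Returns a DataFrame with columns ``subject_id, group, measure,
    direction, value`` — one row per subject and measure component.
    """
    rows = []
    for subject in cohort:
        feats = subject_features(subject, filter_spec, psd_settings, coverage)
        for (measure, direction), value in feats.to_series().items():
            rows.append(
                {
                    "subject_id": subject.subject_id,
                    "group": subject.group,
                    "measure": measure,
                    "direction": direction,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
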