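"""Synthetic faller/nonfaller cohorts of COP recordings.

No raw recordings from the reference study are available, so the package
ships a seeded generator whose contract is statistical structure, not
physiological mechanism:

* Each COP channel is a stationary Ornstein-Uhlenbeck (OU) process — the
  minimal bounded-random-walk model of quiet-stance sway, with amplitude
  ``sigma / sqrt(2 * lambda)`` and bandwidth ``lambda`` separately
  tunable — plus a low-frequency postural oscillation ("tremor")
  sinusoid with a per-subject frequency and per-trial random phase.
* Between-subject heterogeneity is a lognormal amplitude factor shared
  by both channels and the tremor, so that all amplitude-driven measures
  (distance, velocity, area, peak power) co-vary within a subject.
* Clinical scores are tied to that latent amplitude factor through a
  Gaussian copula with configurable rank-correlation targets, so that
  e.g. the Tinetti balance score correlates negatively with sway size.

The generator is fully deterministic under a master seed: subject-level
draws use ``SeedSequence((seed, group_index, subject_index))`` and trial
noise uses ``SeedSequence((seed, group_index, subject_index, trial))``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, signal

from .core import COPTrial, CohortTable, ParameterError, SubjectRecord
from .features import cohort_features
from .preprocess import FilterSpec
from .reference import clinical_summary
from .spectral import PSDSettings

__all__ = [
    "GeneratorParams",
    "ScoreSpec",
    "ClinicalLinkSpec",
    "default_clinical_link",
    "generate_trial",
    "generate_cohort",
    "cohort_feature_means",
    "CalibrationResult",
    "calibrate_params",
    "load_params",
    "save_params",
    "default_params",
]

_GROUP_INDEX = {"faller": 0, "nonfaller": 1}
_TREMOR_FREQ_CLIP = (0.15, 3.0)


@dataclass(frozen=True)
class GeneratorParams:
    """Sway-generator parameters for one group.

    Units: ``lambda_*`` 1/s (mean-reversion rate), ``sigma_*`` mm/sqrt(s)
    (diffusion scale), tremor amplitudes mm, frequencies Hz.
    ``subject_cv`` is the between-subject coefficient of variation of the
    shared lognormal amplitude factor.
    """

    lambda_ap: float
    lambda_ml: float
    sigma_ap: float
    sigma_ml: float
    tremor_amp_ap: float = 0.0
    tremor_amp_ml: float = 0.0
    tremor_freq: float = 0.32
    tremor_freq_sd: float = 0.0
    subject_cv: float = 0.0
    fs: float = 100.0
    duration: float = 30.0
    n_trials: int = 3

    def __post_init__(self) -> None:
        if self.lambda_ap <= 0 or self.lambda_ml <= 0:
            raise ParameterError("mean-reversion rates must be positive")
        if self.sigma_ap < 0 or self.sigma_ml < 0:
            raise ParameterError("diffusion scales must be non-negative")
        if self.tremor_amp_ap < 0 or self.tremor_amp_ml < 0:
            raise ParameterError("tremor amplitudes must be non-negative")
        if not 0.0 <= self.subject_cv < 1.5:
            raise ParameterError("subject_cv must lie in [0, 1.5)")
        if self.tremor_freq_sd < 0:
            raise ParameterError("tremor_freq_sd must be non-negative")
        if not self.fs > 2.0 * self.tremor_freq:
            raise ParameterError("fs must exceed twice the tremor frequency")
        if self.duration <= 0 or self.n_trials < 1:
            raise ParameterError("duration and n_trials must be positive")

    def replace(self, **changes) -> "GeneratorParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ScoreSpec:
    """Marginal (per group) and latent-factor link of one clinical score.

    ``rank_corr`` is the target Spearman correlation between the score
    and the subject's latent sway-amplitude factor; |rank_corr| <= 0.95.
    ``step`` optionally snaps generated values to a grid (e.g. 0.5 for
    the ordinal Hoehn-Yahr stage).
    """

    faller_mean: float
    faller_sd: float
    nonfaller_mean: float
    nonfaller_sd: float
    lo: float = -np.inf
    hi: float = np.inf
    rank_corr: float = 0.0
    step: float | None = None

    def __post_init__(self) -> None:
        if abs(self.rank_corr) > 0.95:
            raise ParameterError("|rank_corr| must be <= 0.95")
        if self.faller_sd < 0 or self.nonfaller_sd < 0:
            raise ParameterError("score SDs must be non-negative")


@dataclass(frozen=True)
class ClinicalLinkSpec:
    """Named clinical scores and their links to the latent sway factor."""

    scores: dict[str, ScoreSpec] = field(default_factory=dict)


# rank-correlation targets between each score and the latent sway
# amplitude: sign-consistent with the published correlation table
# (balance ability down, fear of falling up with larger sway), with
# near-zero links for scores reported uncorrelated
_SCORE_LINKS: dict[str, tuple[float, float, float, float | None]] = {
    # score: (lo, hi, rank_corr, step)
    "age": (40.0, 85.0, 0.0, None),
    "height": (130.0, 190.0, 0.0, None),
    "weight": (35.0, 100.0, 0.0, None),
    "disease_duration": (0.0, 15.0, 0.1, None),
    "education": (0.0, 22.0, 0.0, None),
    "HY_stage": (0.0, 3.0, 0.2, 0.5),
    "UPDRS_III": (0.0, 108.0, 0.08, 1.0),
    "NFOGQ": (0.0, 28.0, 0.15, 1.0),
    "FOF": (0.0, 64.0, 0.35, None),
    "Tinetti_balance": (0.0, 16.0, -0.43, None),
    "K_FAB": (0.0, 18.0, 0.0, None),
    "PHQ_9": (0.0, 27.0, 0.1, None),
    "STAI": (20.0, 80.0, 0.1, None),
}


def default_clinical_link() -> ClinicalLinkSpec:
    """Clinical marginals from the published group table, with default links."""
    table = clinical_summary().set_index("score")
    scores = {}
    for name, (lo, hi, r, step) in _SCORE_LINKS.items():
        row = table.loc[name]
        scores[name] = ScoreSpec(
            faller_mean=float(row.faller_mean),
            faller_sd=float(row.faller_sd),
            nonfaller_mean=float(row.nonfaller_mean),
            nonfaller_sd=float(row.nonfaller_sd),
            lo=lo,
            hi=hi,
            rank_corr=r,
            step=step,
        )
    return ClinicalLinkSpec(scores=scores)


def _ou(lam: float, sigma: float, n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Exact discretization of a stationary OU process.

    ``x[k+1] = x[k] * exp(-lam*dt) + sigma * sqrt((1 - exp(-2*lam*dt)) / (2*lam)) * eps``
    started from the stationary distribution N(0, sigma^2 / (2*lam)).
    """
    a = np.exp(-lam * dt)
    step_sd = sigma * np.sqrt((1.0 - a * a) / (2.0 * lam))
    stat_sd = sigma / np.sqrt(2.0 * lam)
    drive = np.empty(n)
    drive[0] = rng.normal(0.0, stat_sd)
    drive[1:] = rng.normal(0.0, 1.0, n - 1) * step_sd
    # AR(1) recursion via an IIR filter (zero initial state)
    return signal.lfilter([1.0], [1.0, -a], drive)


def generate_trial(params: GeneratorParams, seed) -> COPTrial:
    """One seeded trial: OU sway per channel plus the tremor sinusoid.

    ``seed`` may be an int or anything ``np.random.SeedSequence``
    accepts; the same seed always yields a bit-identical trial.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(params.duration * params.fs))
    dt = 1.0 / params.fs
    t = np.arange(n) * dt
    channels = {}
    for name, lam, sigma, amp in (
        ("ap", params.lambda_ap, params.sigma_ap, params.tremor_amp_ap),
        ("ml", params.lambda_ml, params.sigma_ml, params.tremor_amp_ml),
    ):
        x = _ou(lam, sigma, n, dt, rng)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        if amp > 0:
            x = x + amp * np.sin(2.0 * np.pi * params.tremor_freq * t + phase)
        channels[name] = x
    return COPTrial(ap=channels["ap"], ml=channels["ml"], fs=params.fs)


def _lognormal_factor(cv: float, z: float) -> float:
    """exp of N(mu, s) evaluated at z-score ``z``, with unit mean and CV ``cv``."""
    if cv == 0:
        return 1.0
    s = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(-0.5 * s * s + s * z))


def _subject_params(params: GeneratorParams, g: float, f_trem: float) -> GeneratorParams:
    return params.replace(
        sigma_ap=params.sigma_ap * g,
        sigma_ml=params.sigma_ml * g,
        tremor_amp_ap=params.tremor_amp_ap * g,
        tremor_amp_ml=params.tremor_amp_ml * g,
        tremor_freq=f_trem,
        tremor_freq_sd=0.0,
        subject_cv=0.0,
    )


def _draw_clinical(
    link: ClinicalLinkSpec, group: str, z: float, rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    for name in sorted(link.scores):
        spec = link.scores[name]
        eps = rng.standard_normal()
        if spec.rank_corr != 0.0:
            # Gaussian copula: convert the Spearman target to the
            # corresponding bivariate-normal (Pearson) correlation
            rho = 2.0 * np.sin(np.pi * spec.rank_corr / 6.0)
            u = rho * z + np.sqrt(1.0 - rho * rho) * eps
        else:
            u = eps
        mean, sd = (
            (spec.faller_mean, spec.faller_sd)
            if group == "faller"
            else (spec.nonfaller_mean, spec.nonfaller_sd)
        )
        value = mean + sd * u
        if spec.step:
            value = round(value / spec.step) * spec.step
        out[name] = float(np.clip(value, spec.lo, spec.hi))
    return out


def generate_cohort(
    faller: GeneratorParams,
    nonfaller: GeneratorParams,
    link: ClinicalLinkSpec | None = None,
    n_per_group: int = 32,
    seed: int = 0,
) -> CohortTable:
    """Seeded two-group cohort of subjects with trials and clinical scores.

    Per subject, a latent standard-normal ``z`` sets the lognormal
    amplitude factor (CV = ``subject_cv``) applied to both diffusion
    scales and tremor amplitudes, and feeds the clinical-score copula.
    The subject's tremor frequency is drawn once and shared by all of
    their trials.
    """
    if n_per_group < 2:
        raise ParameterError("need at least 2 subjects per group")
    if link is None:
        link = default_clinical_link()
    subjects = []
    for group, params in (("faller", faller), ("nonfaller", nonfaller)):
        gidx = _GROUP_INDEX[group]
        prefix = "F" if group == "faller" else "N"
        for i in range(n_per_group):
            srng = np.random.default_rng(np.random.SeedSequence((seed, gidx, i)))
            z = float(srng.standard_normal())
            g = _lognormal_factor(params.subject_cv, z)
            f_trem = float(
                np.clip(
                    srng.normal(params.tremor_freq, params.tremor_freq_sd),
                    *_TREMOR_FREQ_CLIP,
                )
            )
            sp = _subject_params(params, g, f_trem)
            trials = tuple(
                generate_trial(sp, (seed, gidx, i, 1 + k))
                for k in range(params.n_trials)
            )
            clinical = _draw_clinical(link, group, z, srng)
            subjects.append(
                SubjectRecord(
                    subject_id=f"{prefix}{i:03d}",
                    group=group,
                    trials=trials,
                    clinical=clinical,
                )
            )
    return CohortTable(subjects=tuple(subjects))


# ---------------------------------------------------------------------------
# calibration


def cohort_feature_means(
    params: GeneratorParams,
    n_subjects: int = 16,
    seed: int = 0,
    filter_spec: FilterSpec = FilterSpec(),
    psd_settings: PSDSettings = PSDSettings(),
) -> pd.Series:
    """Mean extracted features over a single-group cohort.

    Returns a Series indexed by (measure, direction). Used as the forward
    model inside :func:`calibrate_params`.
    """
    subjects = []
    for i in range(n_subjects):
        srng = np.random.default_rng(np.random.SeedSequence((seed, 0, i)))
        z = float(srng.standard_normal())
        g = _lognormal_factor(params.subject_cv, z)
        f_trem = float(
            np.clip(srng.normal(params.tremor_freq, params.tremor_freq_sd), *_TREMOR_FREQ_CLIP)
        )
        sp = _subject_params(params, g, f_trem)
        trials = tuple(
            generate_trial(sp, (seed, 0, i, 1 + k)) for k in range(params.n_trials)
        )
        subjects.append(
            SubjectRecord(subject_id=f"S{i:03d}", group="faller", trials=trials)
        )
    table = cohort_features(CohortTable(tuple(subjects)), filter_spec, psd_settings)
    return table.groupby(["measure", "direction"])["value"].mean()


@dataclass(frozen=True)
class CalibrationResult:
    """Best parameter set found, with achieved means and relative errors."""

    params: GeneratorParams
    achieved: dict[tuple[str, str], float]
    rel_errors: dict[tuple[str, str], float]
    loss: float
    n_evals: int


_SEARCHABLE = (
    "lambda_ap",
    "lambda_ml",
    "sigma_ap",
    "sigma_ml",
    "tremor_amp_ap",
    "tremor_amp_ml",
    "tremor_freq",
    "subject_cv",
)


def calibrate_params(
    targets: dict[tuple[str, str], float],
    search_space: dict[str, tuple[float, float] | float],
    base: GeneratorParams,
    seed: int = 0,
    n_subjects: int = 16,
    max_evals: int = 200,
    weights: dict[tuple[str, str], float] | None = None,
    couple_tremor: bool = False,
) -> CalibrationResult:
    """Fit generator parameters so simulated cohort feature means hit targets.

    Minimizes the weighted squared relative error between simulated group
    feature means and ``targets`` by Nelder-Mead in log-parameter space,
    with common random numbers (a fixed inner seed derived from ``seed``)
    so the objective is deterministic. ``search_space`` maps parameter
    names to (lo, hi) bounds; a scalar (or lo == hi) pins the parameter.

    The inner cohorts are simulated with ``subject_cv = 0``: the targets
    are group means, and the amplitude factor has unit mean, so switching
    off heterogeneity during the search only removes sampling noise.

    ``couple_tremor=True`` ties each channel's tremor amplitude to its
    diffusion scale at the ratio of ``base`` — an amplitude-only search
    that preserves the spectral shape of ``base`` exactly.
    """
    if not targets:
        raise ParameterError("no calibration targets")
    if not search_space:
        raise ParameterError("empty search space")
    weights = weights or {}
    for name in search_space:
        if name not in _SEARCHABLE:
            raise ParameterError(f"cannot search over parameter {name!r}")

    fixed: dict[str, float] = {}
    free: list[str] = []
    bounds: dict[str, tuple[float, float]] = {}
    for name, spec in search_space.items():
        if np.isscalar(spec):
            fixed[name] = float(spec)
        else:
            lo, hi = float(spec[0]), float(spec[1])
            if not 0 < lo <= hi:
                raise ParameterError(f"bounds for {name!r} must satisfy 0 < lo <= hi")
            if lo == hi:
                fixed[name] = lo
            else:
                free.append(name)
                bounds[name] = (lo, hi)

    ratio_ap = base.tremor_amp_ap / base.sigma_ap if couple_tremor else None
    ratio_ml = base.tremor_amp_ml / base.sigma_ml if couple_tremor else None
    inner_seed = (seed * 2654435761 + 0x5CA1B) % (2**31)
    n_evals = 0

    def build(values: dict[str, float]) -> GeneratorParams:
        changes = dict(fixed)
        changes.update(values)
        if couple_tremor:
            if "sigma_ap" in changes:
                changes["tremor_amp_ap"] = changes["sigma_ap"] * ratio_ap
            if "sigma_ml" in changes:
                changes["tremor_amp_ml"] = changes["sigma_ml"] * ratio_ml
        return base.replace(**changes)

    def evaluate(params: GeneratorParams) -> tuple[float, dict, dict]:
        nonlocal n_evals
        n_evals += 1
        means = cohort_feature_means(
            params.replace(subject_cv=0.0), n_subjects=n_subjects, seed=inner_seed
        )
        achieved = {}
        errors = {}
        loss = 0.0
        for key, target in targets.items():
            value = float(means[key])
            achieved[key] = value
            errors[key] = (value - target) / target
            loss += weights.get(key, 1.0) * errors[key] ** 2
        return loss, achieved, errors

    if not free:
        params = build({})
        loss, achieved, errors = evaluate(params)
        return CalibrationResult(params, achieved, errors, loss, n_evals)

    log_lo = np.log([bounds[n][0] for n in free])
    log_hi = np.log([bounds[n][1] for n in free])

    def objective(x: np.ndarray) -> float:
        clipped = np.clip(x, log_lo, log_hi)
        penalty = float(np.sum((x - clipped) ** 2))
        params = build({n: float(np.exp(v)) for n, v in zip(free, clipped)})
        loss, _, _ = evaluate(params)
        return loss + 10.0 * penalty

    # seeded random multi-start: screen log-uniform draws, then polish the
    # best with Nelder-Mead (the objective has local optima in lambda/tremor)
    n_screen = max(8, max_evals // 4)
    srng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    base_x = np.clip(
        np.log([max(getattr(base, n), 1e-12) for n in free]), log_lo, log_hi
    )
    candidates = [base_x, 0.5 * (log_lo + log_hi)] + [
        srng.uniform(log_lo, log_hi) for _ in range(n_screen - 2)
    ]
    x0 = min(candidates, key=objective)
    result = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxfev": max(max_evals - n_screen, 10 * (len(free) + 1)),
                 "xatol": 0.01, "fatol": 1e-4},
    )
    best_x = np.clip(result.x, log_lo, log_hi)
    params = build({n: float(np.exp(v)) for n, v in zip(free, best_x)})
    loss, achieved, errors = evaluate(params)
    return CalibrationResult(params, achieved, errors, loss, n_evals)


# ---------------------------------------------------------------------------
# parameter persistence


def save_params(params: GeneratorParams, path: str | Path) -> None:
    """Write generator parameters as YAML."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=True)


def load_params(path: str | Path) -> GeneratorParams:
    """Read generator parameters from YAML."""
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    return GeneratorParams(**data)


def default_params(group: str) -> GeneratorParams:
    """Shipped calibrated parameters for ``"faller"`` or ``"nonfaller"``.

    Produced by ``scripts/calibrate_configs.py`` against the published
    group feature means; see the methods note for the procedure.
    """
    if group not in _GROUP_INDEX:
        raise ParameterError(f"group must be 'faller' or 'nonfaller', got {group!r}")
    ref = resources.files("swaylab").joinpath(f"configs/{group}.yaml")
    with resources.as_file(ref) as path:
        return load_params(path)
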