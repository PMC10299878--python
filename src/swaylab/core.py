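"""Core containers for center-of-pressure (COP) recordings and cohorts.

A force plate records the COP trajectory of a quietly standing subject as
two displacement channels: anteroposterior (AP, forward-backward) and
mediolateral (ML, side-to-side), in millimetres at a fixed sampling rate.
A subject contributes three 30-s trials plus a set of clinical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COPTrial",
    "SubjectRecord",
    "CohortTable",
    "GROUPS",
    "CLINICAL_SCORES",
    "SwayError",
    "FormatError",
    "ParameterError",
]

GROUPS = ("faller", "nonfaller")

#: Clinical score names carried by a SubjectRecord (a subset may be present).
CLINICAL_SCORES = (
    "age",
    "height",
    "weight",
    "disease_duration",
    "education",
    "HY_stage",
    "UPDRS_III",
    "NFOGQ",
    "FOF",
    "Tinetti_balance",
    "K_FAB",
    "PHQ_9",
    "STAI",
)


class SwayError(Exception):
    """Base class for swaylab errors."""


class FormatError(SwayError):
    """A file did not match the expected trial/cohort format."""


class ParameterError(SwayError, ValueError):
    """A parameter violated its documented constraints."""


@dataclass(frozen=True)
class COPTrial:
    """One COP recording: AP and ML displacement (mm) at sampling rate ``fs`` (Hz)."""

    ap: np.ndarray
    ml: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        ap = np.asarray(self.ap, dtype=float)
        ml = np.asarray(self.ml, dtype=float)
        object.__setattr__(self, "ap", ap)
        object.__setattr__(self, "ml", ml)
        if ap.ndim != 1 or ml.ndim != 1:
            raise ParameterError("COP channels must be one-dimensional")
        if ap.size != ml.size:
            raise ParameterError(
                f"channel lengths differ: ap={ap.size}, ml={ml.size}"
            )
        if ap.size < 2:
            raise ParameterError("a COP trial needs at least 2 samples")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not (np.all(np.isfinite(ap)) and np.all(np.isfinite(ml))):
            raise ParameterError("COP samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.ap.size)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    def replace(self, ap: np.ndarray, ml: np.ndarray) -> "COPTrial":
        """New trial with the same sampling rate and different samples."""
        return COPTrial(ap=ap, ml=ml, fs=self.fs)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: group label, exactly three trials, clinical scores."""

    subject_id: str
    group: str
    trials: tuple[COPTrial, ...]
    clinical: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}, got {self.group!r}")
        object.__setattr__(self, "trials", tuple(self.trials))
        if len(self.trials) != 3:
            raise ParameterError(
                f"subject {self.subject_id!r} has {len(self.trials)} trials, expected 3"
            )
        for name, value in self.clinical.items():
            if value is not None and not np.isfinite(value):
                raise ParameterError(
                    f"clinical score {name!r} of {self.subject_id!r} is not finite"
                )
        hy = self.clinical.get("HY_stage")
        if hy is not None and not 0.0 <= hy <= 5.0:
            raise ParameterError(f"HY_stage must lie in [0, 5], got {hy}")


@dataclass(frozen=True)
class CohortTable:
    """A cohort of subjects with unique identifiers."""

    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ParameterError("subject_id values must be unique")

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GROUPS}
        for s in self.subjects:
            counts[s.group] += 1
        return counts

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)
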