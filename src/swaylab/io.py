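"""Reading and writing COP trials and cohorts, and report formatting.

File conventions
----------------
A trial is a CSV file with the sampling rate in a comment header::

    # fs_hz=100
    cop_ap_mm,cop_ml_mm
    0.1250,-0.3120
    ...

A cohort is a directory with one ``manifest.csv`` (subject_id, group,
three trial paths relative to the directory, clinical score columns) plus
the trial files it names.
"""

from __future__ import annotations

import csv
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CLINICAL_SCORES, COPTrial, CohortTable, FormatError, ParameterError, SubjectRecord

__all__ = [
    "read_trial",
    "write_trial",
    "write_cohort",
    "read_cohort",
    "clinical_table",
    "round_half_up",
    "format_p",
    "format_comparison_table",
]

_FS_KEY = "fs_hz"
_COLUMNS = ("cop_ap_mm", "cop_ml_mm")


def read_trial(path: str | Path) -> COPTrial:
    """Read one trial CSV; see the module docstring for the dialect."""
    path = Path(path)
    fs = None
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                if key.strip() == _FS_KEY:
                    try:
                        fs = float(value)
                    except ValueError:
                        raise FormatError(f"{path}: invalid {_FS_KEY} value {value!r}")
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        if fs is None:
            raise FormatError(f"{path}: missing '# {_FS_KEY}=<value>' header")
        try:
            frame = pd.read_csv(fh, float_precision="round_trip")
        except Exception as exc:
            raise FormatError(f"{path}: unreadable CSV body ({exc})") from exc
    for col in _COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
        if not np.issubdtype(frame[col].dtype, np.number) or frame[col].isna().any():
            raise FormatError(f"{path}: non-numeric sample in column {col!r}")
    if len(frame) < 2:
        raise FormatError(f"{path}: a trial needs at least 2 samples, found {len(frame)}")
    return COPTrial(
        ap=frame[_COLUMNS[0]].to_numpy(float),
        ml=frame[_COLUMNS[1]].to_numpy(float),
        fs=fs,
    )


def write_trial(trial: COPTrial, path: str | Path) -> None:
    """Write a trial CSV readable by :func:`read_trial` with full precision."""
    if str(path) == "":
        raise ParameterError("empty path")
    path = Path(path)
    with path.open("w", newline="") as fh:
        fs = trial.fs
        fh.write(f"# {_FS_KEY}={fs:.12g}\n")
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for a, m in zip(trial.ap, trial.ml):
            writer.writerow((repr(float(a)), repr(float(m))))


def write_cohort(cohort: CohortTable, directory: str | Path) -> None:
    """Write every trial plus a ``manifest.csv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in cohort:
        trial_names = []
        for k, trial in enumerate(subject.trials, start=1):
            name = f"{subject.subject_id}_trial{k}.csv"
            write_trial(trial, directory / name)
            trial_names.append(name)
        row = {"subject_id": subject.subject_id, "group": subject.group}
        row.update({f"trial_{k}": n for k, n in enumerate(trial_names, start=1)})
        row.update({s: subject.clinical.get(s) for s in CLINICAL_SCORES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def read_cohort(directory: str | Path) -> CohortTable:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"{directory}: no manifest.csv")
    frame = pd.read_csv(manifest)
    for col in ("subject_id", "group", "trial_1", "trial_2", "trial_3"):
        if col not in frame.columns:
            raise FormatError(f"{manifest}: missing column {col!r}")
    subjects = []
    for _, row in frame.iterrows():
        trials = tuple(
            read_trial(directory / row[f"trial_{k}"]) for k in (1, 2, 3)
        )
        clinical = {
            s: float(row[s])
            for s in CLINICAL_SCORES
            if s in frame.columns and pd.notna(row[s])
        }
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                trials=trials,
                clinical=clinical,
            )
        )
    return CohortTable(subjects=tuple(subjects))


def clinical_table(cohort: CohortTable) -> pd.DataFrame:
    """Clinical scores as a DataFrame indexed by subject_id."""
    rows = {s.subject_id: dict(s.clinical) for s in cohort}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject_id"
    return frame


# ---------------------------------------------------------------------------
# report formatting


def round_half_up(x: float, decimals: int) -> str:
    """Decimal string of ``x`` rounded half-up to ``decimals`` places."""
    if decimals < 0:
        raise ParameterError("decimals must be >= 0")
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float, decimals: int = 2) -> str:
    """p-value rendering convention: values below 0.001 print as 'P < 0.001'."""
    if p < 0.001:
        return "P < 0.001"
    return round_half_up(p, decimals)


def format_comparison_table(comparisons: list, decimals: int = 2) -> str:
    """Plain-text group comparison table, one row per measure row.

    Columns: measure, direction, group means (SD), and the two-tailed p,
    everything rounded half-up to ``decimals``. A deterministic, purely
    numeric function of its inputs.
    """
    if decimals < 0:
        raise ParameterError("decimals must be >= 0")
    if not comparisons:
        raise ParameterError("no comparisons to format")
    header = ("Measure", "Direction", "Faller Mean (SD)", "Nonfaller Mean (SD)", "p")
    body = []
    for c in comparisons:
        body.append(
            (
                c.measure,
                c.direction,
                f"{round_half_up(c.group1.mean, decimals)} ({round_half_up(c.group1.sd, decimals)})",
                f"{round_half_up(c.group2.mean, decimals)} ({round_half_up(c.group2.sd, decimals)})",
                format_p(c.p, decimals),
            )
        )
    widths = [max(len(r[i]) for r in [header, *body]) for i in range(len(header))]
    lines = []
    for r in [header, tuple("-" * w for w in widths), *body]:
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"
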