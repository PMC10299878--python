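"""Group comparison and correlation statistics for sway features.

The inferential stage mirrors the standard posturography workflow:
independent two-sample t-tests (pooled/Student by default, Welch as an
option) between faller and nonfaller groups for every measure, and
Spearman rank correlations between sway measures and clinical scores over
the pooled cohort. No multiple-testing correction is applied; each row is
reported with its own two-tailed p-value.

``ttest_from_summary`` operates on printed summary statistics
(n, mean, SD), which makes published group tables directly re-testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ParameterError, SwayError
from .features import MEASURES

__all__ = [
    "SummaryStats",
    "GroupComparison",
    "SpearmanResult",
    "ttest_from_summary",
    "ttest_from_samples",
    "spearman",
    "spearman_exact_p",
    "compare_cohort",
    "correlate_cohort",
]


@dataclass(frozen=True)
class SummaryStats:
    """Group size, mean, and sample standard deviation of one measure."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ParameterError(f"need n >= 2, got {self.n}")
        if self.sd < 0:
            raise ParameterError(f"sd must be >= 0, got {self.sd}")

    @classmethod
    def of(cls, x: np.ndarray) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test result for one measure row."""

    measure: str
    direction: str
    group1: SummaryStats
    group2: SummaryStats
    t: float
    df: float
    p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class SpearmanResult:
    """Spearman rank correlation with its t-approximation p-value."""

    rho: float
    p: float
    n: int


def ttest_from_summary(
    g1: SummaryStats,
    g2: SummaryStats,
    variant: str = "pooled",
    measure: str = "",
    direction: str = "none",
    alpha: float = 0.05,
) -> GroupComparison:
    """Independent two-sample t-test from summary statistics.

    ``variant="pooled"`` is the classical Student test (pooled variance,
    df = n1+n2-2); ``variant="welch"`` uses the Welch statistic with
    Satterthwaite degrees of freedom. p is two-tailed.
    """
    if g1.sd == 0 and g2.sd == 0:
        raise ParameterError("both standard deviations are zero; t-test undefined")
    n1, n2 = g1.n, g2.n
    diff = g1.mean - g2.mean
    if variant == "pooled":
        sp2 = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        v1, v2 = g1.sd**2 / n1, g2.sd**2 / n2
        se = np.sqrt(v1 + v2)
        df = float((v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)))
    else:
        raise ParameterError(f"unknown t-test variant {variant!r}")
    t = float(diff / se)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(
        measure=measure, direction=direction, group1=g1, group2=g2,
        t=t, df=df, p=p, alpha=alpha,
    )


def ttest_from_samples(
    x: np.ndarray,
    y: np.ndarray,
    variant: str = "pooled",
    measure: str = "",
    direction: str = "none",
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sample t-test from raw samples.

    Defined as :func:`ttest_from_summary` applied to the samples' own
    n/mean/sd, so the two entry points agree exactly.
    """
    return ttest_from_summary(
        SummaryStats.of(x), SummaryStats.of(y), variant=variant,
        measure=measure, direction=direction, alpha=alpha,
    )


def spearman(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    """Spearman rank correlation with midranks for ties.

    The two-tailed p-value uses the t-approximation
    ``t = rho * sqrt((n-2) / (1-rho^2))`` on n-2 degrees of freedom, the
    standard choice for cohort-sized samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("inputs must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ParameterError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SwayError("constant input; rank correlation undefined")
    rx = sps.rankdata(x)  # midranks for ties
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho=rho, p=p, n=n)


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-tailed permutation p-value for the Spearman statistic.

    Enumerates all n! orderings, so it is only usable for n <= 10; it
    serves as an oracle for the t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 10:
        raise ParameterError("exact permutation p only supported for n <= 10")
    observed = abs(spearman(x, y).rho)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= observed - 1e-12
        total += 1
    return count / total


def _pivot(features: pd.DataFrame) -> pd.DataFrame:
    """Wide per-subject table: index subject_id, columns (measure, direction)."""
    wide = features.pivot_table(
        index=["subject_id", "group"], columns=["measure", "direction"], values="value"
    )
    return wide


def compare_cohort(
    features: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "pooled",
) -> list[GroupComparison]:
    """One t-test per measure row between faller and nonfaller subjects.

    ``features`` is the tidy table from
    :func:`swaylab.features.cohort_features`. Rows follow the canonical
    reporting order (velocity, distance, mean/peak frequency, peak power,
    sway area).
    """
    wide = _pivot(features)
    groups = wide.index.get_level_values("group")
    out: list[GroupComparison] = []
    for measure, direction in MEASURES:
        if (measure, direction) not in wide.columns:
            continue
        col = wide[(measure, direction)]
        x = col[groups == "faller"].to_numpy()
        y = col[groups == "nonfaller"].to_numpy()
        if x.size < 2 or y.size < 2:
            raise ParameterError("each group needs at least 2 subjects")
        out.append(
            ttest_from_samples(
                x, y, variant=variant, measure=measure, direction=direction, alpha=alpha
            )
        )
    if not out:
        raise ParameterError("feature table contains no known measures")
    return out


def correlate_cohort(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    scores: list[str],
) -> pd.DataFrame:
    """Spearman correlations of every measure row with every clinical score.

    ``clinical`` is indexed by subject_id with one column per score. The
    pooled cohort (both groups) is used, matching the published
    correlation analysis. Returns a tidy DataFrame with columns
    ``measure, direction, score, rho, p, n``.
    """
    wide = _pivot(features).droplevel("group")
    rows = []
    for measure, direction in MEASURES:
        if (measure, direction) not in wide.columns:
            continue
        values = wide[(measure, direction)]
        for score in scores:
            if score not in clinical.columns:
                raise ParameterError(f"clinical table has no score {score!r}")
            pair = pd.concat([values, clinical[score]], axis=1, join="inner").dropna()
            if len(pair) < 3:
                raise ParameterError(
                    f"score {score!r} present for fewer than 3 subjects"
                )
            res = spearman(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            rows.append(
                {
                    "measure": measure,
                    "direction": direction,
                    "score": score,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
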