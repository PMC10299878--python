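"""Published group summary statistics for fallers vs nonfallers with
Parkinson's disease on a static-balance (quiet standing) protocol.

Two tables from a published force-plate study of 32 fallers and 32
nonfallers (three 30-s trials per subject, trial-averaged features) are
bundled as data:

* ``clinical_summary()`` — demographics and clinical scores per group
  (mean, SD), e.g. Hoehn-Yahr stage, UPDRS III, fear of falling,
  Tinetti balance.
* ``sway_summary()`` — the six COP outcome measures per group (mean, SD)
  for each direction component.

They serve two purposes: re-testing the published group differences
directly from the summary statistics (``ttest_from_summary``), and
providing calibration targets and clinical marginals for the synthetic
cohort generator. The printed significance column is included verbatim
(``printed_p``) for side-by-side display; it is data, not something this
package computes.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "GROUP_N",
    "clinical_summary",
    "sway_summary",
    "sway_targets",
]

#: Subjects per group in the published study.
GROUP_N = 32

# score, faller mean, faller sd, nonfaller mean, nonfaller sd, printed p
_CLINICAL = [
    ("age", 68.25, 8.44, 67.91, 9.36, "0.88"),
    ("height", 159.13, 8.29, 159.31, 7.91, "0.93"),
    ("weight", 57.91, 8.81, 60.03, 8.73, "0.35"),
    ("disease_duration", 4.48, 3.62, 2.68, 2.57, "0.04"),
    ("education", 8.48, 4.47, 7.72, 3.38, "0.47"),
    ("HY_stage", 2.35, 0.70, 1.95, 0.59, "0.02"),
    ("UPDRS_III", 23.09, 9.87, 19.81, 11.01, "0.22"),
    ("NFOGQ", 17.67, 5.65, 13.78, 10.13, "0.19"),
    ("FOF", 28.03, 11.55, 10.89, 12.77, "P < 0.001"),
    ("Tinetti_balance", 8.88, 3.87, 12.26, 3.48, "P < 0.001"),
    ("K_FAB", 12.00, 5.26, 12.93, 3.71, "0.43"),
    ("PHQ_9", 8.86, 5.06, 5.90, 4.37, "0.02"),
    ("STAI", 41.50, 11.26, 37.30, 10.29, "0.14"),
]

# measure, direction, faller mean, faller sd, nonfaller mean, nonfaller sd, printed p
_SWAY = [
    ("mean_velocity", "overall", 17.41, 9.45, 11.67, 6.12, "0.01"),
    ("mean_velocity", "ap", 12.32, 5.94, 8.87, 5.40, "0.02"),
    ("mean_velocity", "ml", 9.58, 6.95, 5.75, 2.66, "0.01"),
    ("mean_distance", "overall", 7.50, 3.98, 5.67, 1.92, "0.02"),
    ("mean_distance", "ap", 4.96, 2.39, 4.07, 1.49, "0.08"),
    ("mean_distance", "ml", 4.54, 2.93, 3.04, 1.45, "0.01"),
    ("mean_frequency", "overall", 0.40, 0.17, 0.35, 0.16, "0.26"),
    ("mean_frequency", "ap", 0.48, 0.19, 0.43, 0.26, "0.31"),
    ("mean_frequency", "ml", 0.41, 0.22, 0.37, 0.11, "0.33"),
    ("peak_frequency", "overall", 0.40, 0.09, 0.37, 0.07, "0.19"),
    ("peak_frequency", "ap", 0.37, 0.10, 0.35, 0.07, "0.30"),
    ("peak_frequency", "ml", 0.36, 0.11, 0.34, 0.07, "0.29"),
    ("peak_power", "overall", 1031.86, 1130.21, 497.42, 347.01, "0.01"),
    ("peak_power", "ap", 1583.28, 1163.87, 747.42, 351.51, "P < 0.001"),
    ("peak_power", "ml", 1907.72, 2322.22, 843.40, 1376.53, "0.30"),
    ("sway_area", "none", 823.23, 1235.08, 337.20, 192.06, "0.04"),
]

_CLINICAL_COLS = ["score", "faller_mean", "faller_sd", "nonfaller_mean", "nonfaller_sd", "printed_p"]
_SWAY_COLS = ["measure", "direction", "faller_mean", "faller_sd", "nonfaller_mean", "nonfaller_sd", "printed_p"]


def clinical_summary() -> pd.DataFrame:
    """Published clinical/demographic group summaries (n=32 per group)."""
    return pd.DataFrame(_CLINICAL, columns=_CLINICAL_COLS)


def sway_summary() -> pd.DataFrame:
    """Published COP outcome measure group summaries (n=32 per group)."""
    return pd.DataFrame(_SWAY, columns=_SWAY_COLS)


def sway_targets(group: str) -> dict[tuple[str, str], float]:
    """Published feature means of one group, keyed by (measure, direction).

    These are the calibration targets for the synthetic generator.
    """
    col = {"faller": "faller_mean", "nonfaller": "nonfaller_mean"}[group]
    table = sway_summary()
    return {
        (row.measure, row.direction): getattr(row, col)
        for row in table.itertuples(index=False)
    }
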