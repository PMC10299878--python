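"""Spearman correlations between sway measures and clinical scores.

Over the pooled cohort, the Tinetti balance score should correlate
negatively with sway size (better balance, less sway) and the
fear-of-falling score positively; UPDRS III stays near zero.
"""

from swaylab import (
    clinical_table,
    cohort_features,
    correlate_cohort,
    default_params,
    generate_cohort,
)

cohort = generate_cohort(
    default_params("faller"), default_params("nonfaller"), n_per_group=32, seed=0
)
feats = cohort_features(cohort)
scores = ["UPDRS_III", "FOF", "Tinetti_balance"]
table = correlate_cohort(feats, clinical_table(cohort), scores)

wide = table.pivot(index=["measure", "direction"], columns="score", values="rho")
print(wide.round(3)[scores])
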