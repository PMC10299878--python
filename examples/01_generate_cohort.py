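"""Generate a synthetic faller/nonfaller cohort and write it to disk.

Each subject gets three 30-s center-of-pressure trials (AP and ML
displacement in mm at 100 Hz) plus clinical scores tied to their latent
sway amplitude. Everything is reproducible from the master seed.
"""

from pathlib import Path

from swaylab import default_params, generate_cohort, write_cohort

cohort = generate_cohort(
    default_params("faller"), default_params("nonfaller"), n_per_group=4, seed=7
)
out = Path("example_cohort")
write_cohort(cohort, out)

print(f"wrote {len(cohort)} subjects to {out}/ (manifest.csv + trial CSVs)")
for s in cohort:
    t = s.trials[0]
    print(
        f"  {s.subject_id} ({s.group}): {t.duration:.0f}-s trials at {t.fs:.0f} Hz, "
        f"HY stage {s.clinical['HY_stage']}, Tinetti {s.clinical['Tinetti_balance']:.1f}"
    )
# Fallers are generated with larger sway amplitude, so their balance-linked
# clinical scores (e.g. Tinetti) tend to be worse than nonfallers'.
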