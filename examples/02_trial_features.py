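"""Extract the six stabilometric measures from one COP trial.

The trial is low-pass filtered (4th-order Butterworth, 10 Hz, zero
phase) and centred before measurement. Units: mm, mm/s, Hz, mm^2/Hz and
mm^2 for the 95% prediction-ellipse sway area.
"""

from swaylab import default_params, generate_trial, trial_features

trial = generate_trial(default_params("nonfaller"), seed=3)
f = trial_features(trial)

print(f"mean distance  (mm):    overall {f.mean_distance.overall:6.2f}  "
      f"AP {f.mean_distance.ap:6.2f}  ML {f.mean_distance.ml:6.2f}")
print(f"mean velocity  (mm/s):  overall {f.mean_velocity.overall:6.2f}  "
      f"AP {f.mean_velocity.ap:6.2f}  ML {f.mean_velocity.ml:6.2f}")
print(f"mean frequency (Hz):    overall {f.mean_frequency.overall:6.2f}  "
      f"AP {f.mean_frequency.ap:6.2f}  ML {f.mean_frequency.ml:6.2f}")
print(f"peak frequency (Hz):    overall {f.peak_frequency.overall:6.2f}  "
      f"AP {f.peak_frequency.ap:6.2f}  ML {f.peak_frequency.ml:6.2f}")
print(f"peak power (mm^2/Hz):   overall {f.peak_power.overall:6.1f}  "
      f"AP {f.peak_power.ap:6.1f}  ML {f.peak_power.ml:6.1f}")
print(f"sway area (mm^2):       {f.sway_area:6.1f}")
# Larger distance/velocity mean more (and faster) sway; the frequency
# measures describe where the sway power sits in the 0.05-5 Hz band.
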