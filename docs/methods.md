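# Methods

## Signal preparation

COP trials carry AP and ML displacement in mm at a fixed sampling rate
(default 100 Hz, 30 s). Both channels are low-pass filtered with a
4th-order Butterworth at 10 Hz, applied forward-backward (zero phase) —
the conventional stabilometry choice; cutoff, order and phase handling
are parameters of `FilterSpec`. Zero-phase application uses reflective
("even") padding sized from the filter's slowest pole so that edge
transients decay below double precision; this makes filtering commute
with time reversal, which the tests assert. After filtering, each
channel is demeaned per trial, so distances are measured from the mean
COP point. No resampling, gap interpolation or artifact rejection is
performed.

## Outcome measures

Time domain (on the prepared trial):

- mean distance — per axis the mean absolute deviation, overall the
  mean resultant distance. The "overall" convention is the 2-D resultant
  trajectory throughout, which guarantees overall ≥ each directional
  component.
- mean velocity — path length divided by elapsed time (N−1)/fs, i.e.
  the traversed duration between first and last sample, not N/fs.
- sway area — the coverage-p prediction ellipse of the trial's 2×2
  sample covariance: area = π · q · √det Σ with q the χ²(2 df) quantile
  at p (5.991 at the default 0.95). A defensible alternative would be a
  convex hull or a principal-component box; the covariance ellipse is
  the dominant convention and is exactly scale-covariant (area ∝ c²). A
  numerically degenerate covariance (det ≤ 1e−12) yields area 0 with a
  logged warning rather than an exception.

Frequency domain: Welch PSD with 10-s Hann segments, 50% overlap,
one-sided density scaling and constant detrend — 0.1 Hz resolution on a
30-s trial, adequate for sway spectra that peak near 0.3–0.5 Hz.
Measures are taken inside an analysis band of 0.05–5 Hz (excludes the
DC bin and the filtered-out high band; configurable): power-weighted
mean frequency (trapezoidal integration), peak frequency (argmax, ties
to the lowest frequency), and peak power (the maximal density value,
mm²/Hz). AP and ML use their own channels; "overall" uses the resultant
distance series √(AP² + ML²) of the centred trial — the only single
series carrying both directions. This convention is a documented choice:
the resultant series is a nonnegative, nonlinear transform, and its mean
frequency runs systematically above the per-channel values (it cannot
fall much below ≈0.39 Hz under these settings, whatever the generator
parameters).

Per subject, the three trials' feature sets are averaged element-wise
(exactly three by default; relaxable to ≥1).

## Inference

Group comparison is an independent two-sample t-test per measure row,
two-tailed. The default is the pooled (Student) variant with
df = n1+n2−2; Welch with Satterthwaite df is a parameter. At the study's
equal group sizes the two statistics coincide and only df differs, so
the reported pattern is robust to the choice. `ttest_from_summary`
computes the identical quantity from printed (n, mean, SD) triples, and
`ttest_from_samples` is defined as that function applied to the sample's
own summaries, a consistency contract the tests pin to 1e−12. No
multiple-testing correction is applied — each row carries its own p, as
is standard in this literature.

Spearman correlations use midranks for ties and the t-approximation
p-value t = ρ√((n−2)/(1−ρ²)); at the pooled cohort size (n = 64) the
approximation is standard. An exact permutation p (full enumeration,
n ≤ 10) is provided as a test oracle only.

## Synthetic cohorts

The generator's contract is statistical structure, not physiological
mechanism (no inverted-pendulum or neuromuscular-delay modelling). Per
channel, sway is a stationary Ornstein–Uhlenbeck process simulated by
exact discretization (x_{k+1} = x_k e^{−λΔt} + σ√((1−e^{−2λΔt})/2λ)·ε,
started from the stationary law), plus a "postural tremor" sinusoid
with per-subject frequency ~N(0.32, 0.15²) Hz (clipped to 0.15–3 Hz)
and per-trial random phase. AP and ML are independent; cross-correlation
is out of scope. The OU rate λ and scale σ tune bandwidth and amplitude
separately; the tremor supplies the spectral peak that quiet-stance
spectra show near 0.3–0.4 Hz, and its per-subject frequency variability
both gives peak frequency a realistic between-subject spread and makes
the six frequency measures co-vary within a subject.

Between-subject heterogeneity is one lognormal amplitude factor per
subject (unit mean, CV `subject_cv`, default 0.28) applied to both σ's
and both tremor amplitudes, so all amplitude-driven measures co-vary.
The same latent normal score feeds a Gaussian copula for the clinical
scores (Spearman targets converted by ρ = 2 sin(π r_s/6)): Tinetti
−0.43, fear of falling +0.35, UPDRS III +0.08, the remaining scores
near zero, with group-specific marginals from the published clinical
table, clipping to plausible ranges, and 0.5-step rounding for the
ordinal Hoehn–Yahr stage. Determinism: subject-level draws come from
`SeedSequence((seed, group, subject))`, trial noise from
`SeedSequence((seed, group, subject, trial))`.

### Calibration

`calibrate_params` fits parameters by minimizing weighted squared
relative error between simulated cohort feature means and target means,
using Nelder-Mead in log-parameter space after a seeded random
multi-start screen (the objective has local optima in λ and the tremor
amplitudes). Common random numbers — a fixed inner seed and 16 inner
subjects — make the objective deterministic; inner cohorts use
subject_cv = 0, which leaves the targeted means unchanged (the factor
has unit mean) while removing sampling noise.

The shipped configs come from `scripts/calibrate_configs.py` (seed 11,
committed): stage 1 fits the nonfaller group over (λ_ap, λ_ml, σ_ap,
σ_ml, tremor amplitudes) to the published distance and velocity rows
plus overall mean/peak frequency; stage 2 fits the faller group as a
per-channel amplitude rescaling (σ and tremor amplitude move together;
λ and tremor frequency fixed), with velocity targets weighted 2× over
distance. Stage-1 errors land within ±16%, stage-2 within ±13% of the
published means. Design reasons for the constrained stage 2:

- The published per-channel distance and velocity ratios between groups
  are mutually inconsistent with any single scale factor; weighting
  velocity resolves the compromise toward the rows with the weakest
  published effects, and incidentally matches the overall and ML
  distance targets more closely.
- Sharing the spectral shape (λ, tremor frequency distribution) across
  groups makes every frequency measure group-null by construction,
  which is the published finding (no significant frequency
  differences); calibrating each group's frequency means independently
  would instead build in a systematic frequency contrast large enough
  to flag significance in a sizable fraction of cohorts.

Two published magnitudes are deliberately not calibration targets.
`subject_cv` is fixed at 0.28 rather than the ≈0.5 the printed SD/mean
ratios suggest: the generator's dispersion is pure between-subject
signal, whereas the printed SDs fold in day-level and protocol
variability this generator does not emulate, and at CV ≈ 0.5 the
published significance pattern itself would be irreproducible at n = 32
(joint reproduction probability ≈ 0.4). Absolute peak power is also
left uncalibrated: the published peak-power magnitudes (≈500–1900
mm²/Hz) are inconsistent with the published mean distances (≈3–7.5 mm)
under any variance-normalized density estimate — peak × bandwidth would
imply far more signal variance than the distances allow — so the
generator reproduces the peak-power group contrast, not its scale.

## What the synthetic data do and do not show

The generator reproduces: feature means near the published group values
(overall distance, velocity and mean frequency within ±25%), the
published significance pattern (amplitude rows separate the groups,
frequency rows do not) in ≳three-quarters of seeded cohorts at n = 32,
the negative Tinetti / positive FOF correlation signs, right-skewed
dispersion, and near-nominal type-I error under identical group
configs. It does not reproduce: printed SDs (smaller, see above),
absolute peak power, AP–ML coupling, inter-trial drift, or any
waveform-level property of real force-plate data — passing tests
support the pipeline's correctness and the internal consistency of the
published tables, not waveform realism.

## Problem sizes and numerical conventions

End-to-end checks use 20 seeded cohorts of 32 + 32 subjects for the
pattern checks and 100 cohorts of 8 + 8 for null calibration; the
sway-area oracle uses 100 replicates of 3000 Gaussian points. Reports
round half-up to 2 decimals and render p < 0.001 as "P < 0.001",
matching the reference tables' conventions. Degenerate inputs follow
the rules above (zero-variance t-tests and constant-input correlations
raise; degenerate covariance returns area 0 with a warning).

## Known limitations

Filter parameters of the reference protocol are unpublished; the
defaults are conventional, so exact numerical agreement with any
specific laboratory's feature values is not claimed — only the
published summary-statistic inference is reproduced exactly. The
"overall" spectral convention is one of several defensible definitions.
Clinical copula targets are sign-calibrated, not fitted to the full
published correlation matrix.
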