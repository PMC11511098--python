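# Methods

This note documents the models, parameter choices and numerical decisions
behind `emghoa`, and what the synthetic-cohort tests do and do not establish
about real recordings.

## Signal conditioning

Two paths are applied to each raw task recording (mV, 1000 Hz):

* **Amplitude path** — 4th-order Butterworth band-pass 25–500 Hz, then
  4th-order Butterworth band-stop 49.5–50.5 Hz, both applied
  forward–backward (zero phase, effective 8th-order magnitude response);
  full-wave rectification; Gaussian smoothing; linear-interpolation
  resampling to exactly 1000 frames (grid includes both endpoints, so
  endpoint values are preserved and monotone segments stay monotone).
* **Waveform path** — the 25–500 Hz band-pass only; the native length is
  kept because the waveform features are explicitly length-normalized. A
  flag can additionally apply the power-line notch on this path.

Numerical choices:

* At 1000 Hz the 500 Hz band-pass edge coincides with Nyquist, where a
  band-pass is unrealizable; the filter degenerates to a 25 Hz high-pass,
  leaving the pass-band unchanged.
* `scipy`'s default forward–backward padding (a few dozen samples) is far
  too short for the 1 Hz-wide notch, whose impulse response rings for
  seconds; padding is extended to min(signal − 1, 3 s) for the notch and
  0.5 s for the band-pass so both reach their design response mid-signal.
  A consequence worth knowing: the notch's ringing exceeds any task-length
  record, so its output is only approximately symmetric under time reversal
  (≈1 % of signal RMS at the edges); the band-pass satisfies the reversal
  identity to ~1e−13. A frequency-domain exact-zero-phase notch was
  evaluated and rejected because its ~10 s kernel smears boundary artifacts
  across the whole record.
* Smoothing sigma defaults to **50 ms** (a typical sEMG envelope scale;
  configurable), kernel truncated at ±4σ, unit-sum normalized, reflect
  padding.

## Normalization

MAX / MVC / GRASP denominators are the peak of the filtered, rectified,
smoothed envelope over the relevant task family, taken **before** the
1000-frame resampling (resampling can clip the true peak); the division is
applied to the resampled envelope. Hence the MAX-normalized peak across a
participant's functional tasks is ≤ 1 and equals 1 up to the interpolation
deficit (< ~1 % at the default smoothing scale). MVC or GRASP denominators
may legitimately be smaller than a functional-task peak, so normalized
values above 1 are allowed. A single global maximum is used — no top-k
averaging.

## Features

* Median of the even-length 1000-frame envelope = mean of the two middle
  order statistics.
* NZC counts **strict** sign changes; a sample exactly at zero breaks the
  change (zeros have measure zero after filtering).
* The EWL exponent window `0.2L ≤ i ≤ 0.8L` is evaluated on the 1-based
  integer index against the real-valued bounds, without rounding; the index
  `i` refers to the leading sample of each difference, running 2..L.
* Both rates are scaled by 1000/L (a per-second rate at 1000 Hz), making
  tasks of different durations comparable.
* Min–max rescaling is per participant × sensor over that participant's
  functional tasks; the degenerate all-equal case maps to 0 with a logged
  warning (it cannot occur with continuous data). Raw rates are retained
  alongside the rescaled values.
* Scale behaviour: normalized amplitude features and NZC are exactly
  invariant to a uniform positive rescaling of a participant's signals;
  rescaled EWL is only approximately invariant because the sum mixes
  exponents 0.5 and 0.75, which scale by c^0.5 and c^0.75 respectively.

## Group statistics

* Per feature cell (sensor × parameter, overall or per task): Shapiro–Wilk
  at α = 0.05 in each group gates one-way ANOVA vs Kruskal–Wallis; the
  direction of a significant difference comes from group means (ANOVA) or
  mean ranks (Kruskal–Wallis). Constant data is treated as non-normal and
  logged. No multiplicity correction is applied across the grid by default,
  mirroring common reporting practice; Benjamini–Hochberg is available via
  a flag. The gate is applied per cell.
* The mixed repeated-measures ANOVA (group between subjects; sensor and
  method within) is computed per error stratum: between-subject effects are
  tested against subjects-within-groups, each within effect against its own
  interaction-with-subjects stratum. With unequal group sizes, within-
  stratum sums of squares use unweighted marginal means with the harmonic
  mean of the group sizes (Type III style); for balanced groups this
  reduces exactly to the textbook decomposition, which is how it is
  validated. No sphericity correction is applied by default.
* Tukey's-B homogeneous subsets: the critical range for a span of r sorted
  means averages the studentized-range quantiles q(α, k, df) and
  q(α, r, df) times √(MS_error/n); maximal contiguous runs whose range
  stays below the critical value form the subsets.

## Discriminant analysis

* Candidates are restricted to features that differed significantly between
  groups. Box's M (chi-square approximation) is computed on each candidate
  set; a violation is logged and the analysis proceeds.
* Stepwise selection: the candidate minimizing the partial Wilks' Λ enters
  when its F-test p-value (df = (g−1, N−g−q)) is below 0.05; after each
  entry, included variables with removal p above 0.10 exit, worst first.
  Ties break on smaller p, then lower sensor index, then
  amplitude-before-waveform. A variable removed at one step cannot re-enter
  at the next, and steps are capped at twice the candidate count, so the
  procedure terminates. Candidates whose addition makes the total SSCP
  numerically singular (condition number > 1e10) are skipped, which also
  guards against duplicated variables.
* The fitted score is the Fisher raw-score discriminant
  `w = S_pooled^{-1}(μ_h − μ_p)` with the cut at the midpoint of the group
  score means (equal priors), oriented so patients score negative; a score
  of exactly zero classifies healthy.
* LOOCV refits coefficients on each fold but keeps the variable set fixed
  from the full-data stepwise pass (the convention of classical statistical
  packages); a strict mode re-runs selection inside each fold for
  sensitivity analysis.
* The five published classifiers are frozen built-ins. The no-MVC combined
  formula was printed with an ellipsis between its amplitude and waveform
  terms; only the four printed terms are included and the definition
  carries an `incomplete` flag. At all-zero predictors its score equals the
  constant term (1.109) regardless of any omitted terms.

## Synthetic cohorts

Each recording is `envelope × unit-RMS band-limited Gaussian noise +
baseline noise` — the standard surrogate for an sEMG interference signal.
Defaults emulate the study layout: 21 healthy vs 20 patient women, 7
sensors at 1000 Hz, 20 functional + 7 MVC + 6 grasp tasks, ~4 s per task
with ±25 % duration jitter (so the per-second scaling of NZC/EWL is
genuinely exercised), noise band 60–350 Hz, baseline 0.005 mV.

Latent per-participant parameters (returned as ground truth): per-sensor
peak amplitudes (lognormal around 0.3 mV, drawn independently per sensor so
sensor-level features are nearly independent), noise-band edges, and effect
parameters. Functional-task envelopes are sums of 1–4 smooth bursts with
random timing/width/height; maximal efforts are trapezoidal
ramp-hold-ramp profiles.

Three injectable group effects, each aimed at one feature family:

| effect | default | drives |
| --- | --- | --- |
| `mvc_amplitude_scale` | 0.75 | MVC/GRASP denominators → MVC/GRASP-normalized amplitude features (values < 1 model pain-limited maximal effort) |
| `envelope_complexity_shift` | 1.0 | Poisson-distributed extra envelope bursts → raw EWL (bursts are added, not sharpened, so the direction is unambiguous) |
| `spectral_shift_hz` | 10 | upward shift of the interference band → NZC |

All sensors are affected by default (amplitude effects were reported across
sensors in the motivating work). The effect magnitudes are the package's
fixed study conditions, chosen once as a moderate, clearly detectable
deviation; they produce stronger group separation than a real clinical
cohort, so cross-validated accuracies on default synthetic cohorts should
not be read as clinical performance estimates.

Every (participant, family, task, sensor) tuple draws from an independent
`SeedSequence` substream keyed on the cohort seed: a fixed seed yields a
bit-identical cohort regardless of generation order, and paired
configurations sharing a seed support variance-reduced comparisons.

What the generator does **not** emulate: motor-unit physiology, electrode
crosstalk and placement shifts, non-stationary fatigue effects, age
structure (an optional knob exists, off by default), power-line
interference, and movement artifacts. Passing tests therefore establish the
correctness and calibration of the computations, not clinical validity.

## Test problem sizes

Monte-Carlo suites run on reduced cohorts: null calibration uses 200 seeded
cohorts of 10+10 participants, 4 sensors, 5 functional + 2+2 maximal tasks
of 1 s, with one feature cell per sensor (median-MAX, range-MAX, NZC, EWL
on distinct sensors, which are nearly independent by construction), and
checks the pooled rejection count against the central 95 % binomial
interval at α = 0.05. Effect recovery uses 50 seeded cohorts of 15+15
participants (4 sensors, 5+3+3 tasks of 1 s) with maximal-effort amplitude
scaled by 0.6 on sensors 2 and 4, requiring the stepwise discriminant to
select an injected sensor in ≥ 90 % of runs and to beat the
permuted-label LOOCV baseline by ≥ 20 accuracy points.

## Known limitations

* The mixed RM-ANOVA's unweighted-means Type III analog is exact for
  balanced groups and a standard approximation for mildly unbalanced ones
  (21 vs 20 here); strongly unbalanced designs would warrant a full GLM.
* The notch filter's zero-phase ideal is unattainable on task-length
  records (see above); in practice the synthetic data contains no 50 Hz
  component and the envelope smoothing absorbs the residual transients.
* Kruskal–Wallis direction uses mean ranks, which can disagree with a
  difference of means for strongly skewed cells.
* `evaluate_published_classifier` applies the printed coefficients to
  task-averaged features; whether those printed formulas are raw-score
  (unstandardized) discriminants is assumed from their direct application
  to parameter values.
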