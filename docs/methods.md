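# Methods

`judoperf` reimplements, as tested library code over synthetic data, the
computational chain of a two-group altitude-training study in elite judokas:
IMU-based kinematic landmark extraction for the *ippon-seoi-nage* throw,
loaded-countermovement-jump (CMJ) load-velocity profiling, and a
baseline-adjusted mixed-model / BCa-bootstrap / standardized-effect
inference pipeline. The study's raw data were never deposited, so every
input is generated by the package's own seeded simulators, with ground
truth stored separately from the noisy signals; the reported group sizes
(13 hypoxia / 11 normoxia), timepoints (Pre, Post-0, Post-1, Post-2),
sampling rate (1 kHz) and baseline descriptives define the default study
conditions.

## Synthetic-data generator (`judoperf.synthetic`)

**Subject panel.** Body mass ~ N(84.54, 19.17²) kg; individual
load-velocity lines for peak velocity (PV) and mean propulsive velocity
(MPV): PV intercept ~ N(3.0, 0.22²) m/s (matching the reported maximal
theoretical velocity V0), PV slope ~ N(−0.014, 0.0015²) (m/s)/kg (so the
load intercept L0 ≈ 210 kg and profile slope ≈ −71 kg·s/m match the
reported magnitudes), MPV intercept = PV intercept − offset with offset
~ N(1.5, 0.10²) m/s, MPV slope ~ N(−0.0075, 0.0008²) (placing the 1RM —
the load at MPV 0.33 m/s — near the reported 1.86 kg/kg of body mass).
Samplers are rejection-truncated only to guard physical ranges; in
particular the MPV intercept is kept above 1.25 m/s so the 1.2 m/s
velocity-based load prescription is defined for every athlete.

**Throw waveform.** The resultant acceleration AccelT is a 1 G rest
baseline plus three Gaussian bumps (default SD 40 ms) peaking at the
off-balance / leg-extension / impact times with the configured amplitudes;
defaults are the reported hypoxia pre-training means (399/898/1172 ms,
6.4/3.0/26.4 G). The transversal angular velocity GyroY is flat before
onset, then a small fast smoothstep deviation (0.5 rad/s over 2 ms, which
makes onset detectable within about one sample) followed by a logistic rise
(amplitude 6 rad/s, scale 70 ms) whose inflection sits at the configured
time-to-horizontal (default 818 ms). This is the simplest smooth family
whose landmarks are analytically known. Noise is additive white Gaussian
per channel; no drift or bias is modeled. Ground truth always echoes the
parameters and is never re-measured from the signal.

**Jump trace.** Rest → sinusoidal countermovement dip (−0.8 m/s over
0.35 s) → concentric rise `PV·(t/T)^p` over 0.3 s → post-peak deceleration
at −20 m/s² (steeper than −9.81, which terminates the propulsive phase at
the peak). The exponent p is calibrated by root-finding so that applying
the package's own propulsive-phase rule to the noiseless series returns the
subject's true MPV exactly; the series maximum is the true PV exactly.
Flight time is taken as 2·PV/g (a deliberate simplification — takeoff
velocity is not modeled separately).

**Study table.** One row per subject × timepoint × outcome. Raw-scale
outcomes: value = subject level + additive group×time effect + N(0, σ_ε)
noise; log-scale outcomes follow the same model on the natural-log scale
(hence log-normal values, multiplicative effects, and geometric mean ⋇
geometric SD as the natural descriptives). Baseline variance splits into a
between-subject share (ICC 0.7, a typical test–retest reliability for
trained athletes' jump and throw measures) and a residual share. Default
outcome levels and dispersions are the reported pre-training descriptives,
and the default injected hypoxia effects are the reported adjusted
between-group differences (e.g. +3.22 cm jump height at Post-0, ×0.73
leg-extension acceleration at Post-1). The seven kinematic outcomes are
drawn independently per cell, so jointly impossible phase orderings can
occur in the tails; the measured chain clips and logs such cells (see
below).

What the generator does **not** emulate: within-throw correlation between
landmarks, sensor drift/bias, inter-repetition variability structure,
learning/fatigue trends, or any physiological mechanism. Passing tests
certify the detectors and the inference machinery against this generative
family, not against real Wimu/T-Force recordings.

## IMU landmark extraction (`judoperf.imu`)

* **Onset**: first time |GyroY − baseline mean| exceeds
  max(3 × baseline SD, 0.1 rad/s) continuously for ≥ 50 ms (the 50 ms
  sustain rule is the protocol's; the multiplier and floor are detector
  choices). The baseline is the first 200 ms of pre-trial rest; the
  absolute deviation is used because the fall direction is not fixed.
* **AccelT peaks**: local maxima of the 30 Hz zero-phase-filtered resultant
  acceleration after onset with prominence ≥ 0.3 G and separation ≥ 100 ms.
  The impact peak must be the post-onset global maximum; the two most
  prominent maxima preceding it are reported in temporal order. 0.3 G sits
  well above smoothed-noise prominences (~0.05 G at 0.05 G channel noise)
  while admitting the weakest observed leg-extension peaks (~1.4 G above a
  1 G baseline).
* **Time-to-horizontal (Thor)**: GyroY over [onset, end] is min–max
  normalized, low-pass filtered at 10 Hz (4th-order zero-phase Butterworth;
  raw 1 kHz differentiation is noise-dominated), and differentiated by
  central differences. Thor is the downward zero-crossing of the second
  derivative with the largest first derivative — the steepest-rise
  inflection — with 150 ms excluded at each end for the filter transient,
  sub-sample refined by linear interpolation of the curvature. A
  numerically linear rise (first derivative varying by < 5%) raises
  `LandmarkNotFound` instead of returning a round-off inflection.
* **Repetition choice**: the worst-rated of the three repetitions is
  excluded (rating ties: the slowest Thor goes), then the quickest-Thor
  repetition is kept. Interrater agreement is summarized by Cronbach's
  alpha with raters as scale items.

All times are reported in ms relative to onset (onset itself absolute).
On noiseless synthetic throws, extraction recovers all landmarks within one
sampling interval plus the one-sample onset latency (≤ 2 ms, magnitudes
within 0.01%); with 0.05 G / 0.02 rad/s channel noise, within ±10 ms across
100 seeds.

## Jump profiling (`judoperf.jumps`)

The propulsive phase is the concentric stretch containing the velocity
peak, from the upward zero-crossing preceding the peak to the first sample
whose central-difference acceleration falls below −9.81 m/s² (or the
concentric end). MPV is the mean over that segment; PV is the trace
maximum; g is fixed at 9.81 m/s². An optional low-pass (`smooth_cutoff`)
is applied before segmentation for noisy recordings — commercial
transducers filter before differentiating — and is off by default.

Per athlete, ordinary least squares through the per-load best repetitions
(highest PV per load) gives the PV and MPV lines. Derived quantities:
1RM = load at MPV 0.33 m/s on the MPV line (and /body mass); V0, L0 and
slope = −L0/V0 from the **PV** line by default — the printed V0 range
(2.95–3.20 m/s) and slope (≈ −71 kg·s/m) match peak-velocity intercepts,
not MPV intercepts, so the PV line is the default source, configurable to
MPV. PV at 25/50/75/100% body mass evaluates the PV line. Jump height
from flight time is g·t²/8 (in cm). The velocity-based training load is
the load at MPV 1.2 m/s from a freshly fitted incremental-test line; 1RM
and 100%-body-mass evaluations may extrapolate beyond the 20–80 kg
protocol and are flagged.

## Inference (`judoperf.inference`, `judoperf.mixedmodel`)

Per outcome, the model for the three post-training timepoints is

    y_it = β0 + β_b (baseline_i − b̄) + time_t + group_g + (time×group)_gt + u_i + ε_it

with a subject random intercept, fitted by REML. The baseline (Pre) score
enters as a covariate of no interest, centered at its grand mean, so the
adjusted between-group contrast at timepoint t (hypoxia − normoxia from the
estimated marginal means) is simply the group coefficient plus the
interaction coefficient. Subjects without a baseline are dropped per
outcome and logged.

The REML solver exploits the single-variance-ratio structure of the
random-intercept model: with λ = τ²/σ², each cluster's covariance inverts
in closed form, σ² profiles out analytically, and a one-dimensional search
over λ remains. Cluster contributions enter only through per-cluster
sufficient statistics, so bootstrap resamples refit by re-summing
precomputed blocks (~1 ms per refit). Fixed effects, variance components,
Satterthwaite df and p-values were cross-checked against statsmodels
MixedLM and R lme4/lmerTest (the statsmodels route remains available via
`engine="mixedlm"`).

**Scale decision.** Precedence: explicit override → the dataset's scale
registry (the recorded analysis decision) → the residual diagnostic:
Spearman ρ between |residual| and fitted value on the raw fit, log if
ρ > 0.3 and all values (response and baseline) are positive. The rule is a
quantitative stand-in for qualitative residual inspection; at realistic
dispersions (geometric SD ≈ 1.3–1.5, n ≈ 12/group) its power is limited,
which is why the registry takes precedence when present. Log-scale
contrasts are reported exponentiated (multiplicative effects, ratio-scale
intervals).

**Uncertainty.** 90% compatibility intervals by the bias-corrected and
accelerated bootstrap: subjects resampled with replacement, stratified by
group so both arms persist (unstratified available), the full model refitted
per replicate with the same scale decision; z₀ = Φ⁻¹(fraction of replicates
below the point estimate), acceleration from the delete-one-subject
jackknife skewness; degenerate replicate sets yield a zero-width interval
with a warning and > 10% replicate failures raise. 500 replicates by
default. p-values use t distributions with Satterthwaite df from the
standard variance-of-variance approximation (numeric REML Hessian); at a
boundary variance the model degenerates to OLS and the residual df is used,
flagged. Standardized mean differences divide the adjusted effect by the
n−1-pooled baseline SD (natural-log effects over pooled log geometric SDs)
and are labelled on the 0.0/0.2/0.6/1.2/2.0/4.0 scale with lower-inclusive
bins.

**Calibration, measured by the acceptance suite.** Under the null design at
n = 13/11, the Post-0 contrast rejects at α = 0.10 in ≈ 10% of 1000
replicates. The 90% BCa interval covers zero in ≈ 86–88% of 300 null
replicates at 500 bootstrap replicates: a known small-sample property of
cluster resampling with ~12 clusters per arm (the bootstrap spread
underestimates the sampling spread by roughly √((n−1)/n) per group), not a
defect of the BCa correction — plain percentile intervals behave the same.
Injected effects are recovered without bias as n grows (≈ 1% at
200/group, averaged over replicates).

## Workflow and problem sizes

`cmd_simulate` writes the seeded study fixture (CSV + truth JSON).
`cmd_analyze` re-measures the seven kinematic outcomes through the full
chain — each subject×timepoint cell parameterizes a simulated throw, three
rated repetitions are extracted and the selection rule keeps one — before
modeling; cells whose independently drawn values violate the waveform's
phase-ordering requirements are clipped and logged, and extraction failures
fall back to the table value, logged. Jump and strength outcomes enter the
model from the study table; their measurement chain (trace → MPV → fits →
profile) runs in the `profile` stage and analysis script 03.

Default problem sizes keep the full test suite and the acceptance script in
the minutes range on one core: 100-seed noisy landmark batches, 150-replicate
1RM-bias studies, 1000-replicate type-I and 300-replicate coverage studies
(B = 500), and 30×(200/group) effect-recovery runs; these sizes are stated
in the tests and scripts that use them.

## Known limitations

* The generator's independence of kinematic outcomes across landmarks and
  timepoints is a simplification; joint orderings are enforced only at
  trace-synthesis time.
* Flight time is tied to PV by a constant; jump-height and PV outcomes are
  therefore not independently informative in trace-level simulations.
* The BCa interval inherits the small-cluster undercoverage described
  above; at the study's size its effective coverage is nearer 86% than 90%.
* No multiple-testing adjustment is applied (none is part of the emulated
  analysis); p-values are secondary to the estimation-style summaries.
* `choose_scale` is a heuristic with limited power at small n; overriding
  by registry or configuration is the intended production path.
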