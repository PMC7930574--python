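# judoperf

Toolkit for analyzing the effect of a 3-week altitude training camp on the
explosive strength and throwing technique of elite judokas. It is built for
sport scientists who work with (a) loaded countermovement-jump (CMJ) tests
on a Smith machine with a linear bar-velocity transducer, (b) wearable-IMU
recordings of the *ippon-seoi-nage* throw executed on an instrumented
dummy, and (c) the parallel-group, repeated-measures inference that such
studies require. Because the original raw recordings are not public, the
package ships a seeded synthetic-study generator whose ground truth makes
every stage testable end to end.

## What it computes

**Throw kinematics** (`judoperf.imu`) — from a tri-axial accelerometer +
gyroscope trace sampled at 1 kHz: movement onset (sustained GyroY deviation
≥ 50 ms), the three peaks of the resultant acceleration
AccelT = √(aₓ² + a_y² + a_z²) — off-balance, leg extension, impact — as
times from onset (Tpeak1/2/3) and magnitudes (Max1/2/3), and the time to
the dummy's horizontal position (Thor, the steepest-rise inflection of the
normalized GyroY). Plus the repetition-selection rule (worst rating out,
quickest Thor in) and Cronbach's alpha for interrater reliability.

**Load-velocity profiling** (`judoperf.jumps`) — peak velocity (PV) and
mean propulsive velocity (MPV, the concentric portion with acceleration ≥
−9.81 m/s²) per jump; first-order fits v = v₀ + b·load per athlete; the
1RM as the load at MPV = 0.33 m/s; V0, L0 and slope = −L0/V0; PV at
25–100% body mass; jump height g·t²/8 from flight time; and the
velocity-based training load at MPV = 1.2 m/s.

**Inference** (`judoperf.inference`) — per outcome, a linear mixed model on
the post-training timepoints with the baseline score as covariate, fixed
time × group effects and a subject random intercept (REML); adjusted
between-group contrasts from the estimated marginal means at each
timepoint; 90% BCa compatibility intervals from subject-level stratified
resampling with full model refits; standardized mean differences
SMD = adjusted effect / pooled baseline SD (log scale for multiplicative
outcomes) with trivial/small/moderate/large/very large/nearly perfect
labels; Satterthwaite-df p-values. Heteroscedastic outcomes (residual
spread growing with the fitted level) are log-transformed and reported as
ratios.

## Worked example

The published effect-size arithmetic can be reproduced directly from the
printed adjusted effects and baseline dispersions (n = 13/11):

```sh
$ judoperf worked-examples
label,outcome,timepoint,scale,effect,sd_hypoxia,n_hypoxia,sd_normoxia,n_normoxia,es_computed,es_printed,match
"jump height, Post-0",jump_height_cm,Post-0,raw,3.22,5.02,13,5.97,11,0.59,0.59,True
"jump height, Post-1",jump_height_cm,Post-1,raw,1.81,5.02,13,5.97,11,0.33,0.33,True
"time to horizontal, Post-0",thor_ms,Post-0,raw,112.0,105.0,13,152.0,11,0.87,0.87,True
"leg-extension accel, Post-1",max2_G,Post-1,log,0.73,1.31,13,1.35,11,-1.11,-1.11,True
"impact accel, Post-0",max3_G,Post-0,log,1.45,1.62,13,1.45,11,0.85,0.85,True
```

Reading the first row: the +3.22 cm adjusted jump-height benefit of the
hypoxia group right after the camp, divided by the pooled baseline SD
√((12·5.02² + 10·5.97²)/22) = 5.47 cm, is a *small* standardized effect of
0.59 — exactly the printed value. The fourth row works on the log scale:
ln(0.73)/pooled(ln 1.31, ln 1.35) = −1.11, a *moderate* detriment to the
leg-extension acceleration one week after the camp.

The full synthetic pipeline runs as numbered drivers:

```sh
python analysis/01_simulate_study.py    # 24 subjects × 4 timepoints × 10 outcomes
python analysis/02_extract_landmarks.py # throws → landmarks, selection, alpha
python analysis/03_jump_profiles.py     # loaded jumps → 1RM, V0/L0/slope, 1.2 m/s load
python analysis/04_adjusted_effects.py  # mixed models → contrasts, BCa CIs, SMDs
python analysis/05_worked_examples.py
```

`04_adjusted_effects.py` prints the study-style results table next to the
effects the generator injected, e.g. (seed 7, B = 100):

```
       outcome timepoint scale  adjusted_diff  ci_low  ci_high     es  es_label     p  injected
jump_height_cm    Post-0   raw          2.597  -1.390    4.169  0.476     small 0.104      3.22
        max2_G    Post-1   log          0.726   0.574    0.805 -0.946  moderate 0.000      0.73
```

— at n = 13/11 a single study scatters around the injected truth
(2.60 vs 3.22 cm; ratio 0.726 vs 0.73); unbiased recovery as n grows is
certified by the acceptance suite (mean estimate 3.21 cm over 30 studies at
n = 200/group). The same workflow is scriptable via the
`judoperf` CLI (`simulate`, `landmarks`, `profile`, `analyze`,
`worked-examples`) with `--config`, `--seed`, `--out`, `--bootstrap-reps`,
`--level`, `--source-fit`.

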