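"""Seeded synthetic study generator with known ground truth.

The emulated study follows a two-group (hypoxia n = 13, normoxia n = 11),
four-timepoint (Pre, Post-0, Post-1, Post-2) parallel design in elite male
judokas.  The generator produces, with a single seed:

* a subject panel with body mass and individual linear load-velocity
  profiles (peak-velocity and mean-propulsive-velocity lines),
* bar-velocity traces of loaded countermovement jumps whose propulsive
  phase reproduces the subject's configured PV/MPV exactly in noiseless
  mode,
* IMU throw traces whose resultant acceleration carries three Gaussian
  bumps at the configured off-balance / leg-extension / impact times and
  whose transversal angular velocity is a logistic rise inflecting at the
  configured time-to-horizontal,
* a long-format study table in which raw-scale outcomes receive additive
  group×time effects and log-scale outcomes multiplicative (log-normal)
  effects.

Stored ground truth is always the configured parameter, never a quantity
re-measured from the noisy signal, so detector and pipeline recovery can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import GROUPS, StudyDataset, TIMEPOINTS
from .errors import DesignError
from .imu import ImuTrace, TechniqueLandmarks
from .jumps import mean_propulsive_velocity

__all__ = [
    "SubjectTruth",
    "ThrowPhaseParams",
    "OutcomeSpec",
    "StudyDesignConfig",
    "simulate_subject_panel",
    "simulate_jump_velocity_trace",
    "simulate_imu_repetition",
    "simulate_study",
    "default_study_config",
    "null_study_config",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SubjectTruth:
    """Per-subject ground truth: identity, mass and load-velocity lines."""

    subject_id: str
    group: str
    body_mass: float            # kg
    true_pv_intercept: float    # m/s
    true_pv_slope: float        # (m/s)/kg, negative
    true_mpv_intercept: float   # m/s
    true_mpv_slope: float       # (m/s)/kg, negative
    outcome_baselines: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.body_mass <= 0:
            raise DesignError("body_mass must be positive")
        if self.true_pv_slope >= 0 or self.true_mpv_slope >= 0:
            raise DesignError("load-velocity slopes must be negative")
        if self.true_pv_intercept <= self.true_mpv_intercept:
            raise DesignError("peak-velocity intercept must exceed the MPV intercept")

    def true_pv(self, load: float) -> float:
        return self.true_pv_intercept + self.true_pv_slope * load

    def true_mpv(self, load: float) -> float:
        return self.true_mpv_intercept + self.true_mpv_slope * load


@dataclass(frozen=True)
class ThrowPhaseParams:
    """Waveform parameters of one simulated *ippon-seoi-nage* repetition.

    Times are ms; ``onset_time`` is absolute within the recording, the phase
    times are relative to onset.  Amplitudes are the AccelT values at the
    three peaks (off-balance, leg extension, impact), riding on a 1 G rest
    baseline.
    """

    onset_time: float = 300.0
    t_offbalance: float = 399.0
    t_legext: float = 898.0
    t_impact: float = 1172.0
    t_horizontal: float = 818.0
    a_offbalance: float = 6.4
    a_legext: float = 3.0
    a_impact: float = 26.4
    peak_width: float = 40.0        # ms, Gaussian SD of the AccelT bumps
    noise_sd_accel: float = 0.0     # G, per channel
    noise_sd_gyro: float = 0.0      # rad/s, per channel
    gyro_amplitude: float = 6.0     # rad/s, plateau of the main GyroY rise
    gyro_rise_scale: float = 70.0   # ms, logistic scale of the main rise
    onset_step: float = 0.5         # rad/s, small fast deviation that marks onset
    onset_step_width: float = 2.0   # ms
    tail: float = 400.0             # ms recorded after impact

    def __post_init__(self):
        if not (0 < self.t_offbalance < self.t_legext < self.t_impact):
            raise DesignError("phase times must satisfy 0 < off-balance < leg extension < impact")
        if not (0 < self.t_horizontal < self.t_impact):
            raise DesignError("time-to-horizontal must lie strictly between onset and impact")
        if min(self.a_offbalance, self.a_legext, self.a_impact) <= 0:
            raise DesignError("peak amplitudes must be positive")

    def replace(self, **kw) -> "ThrowPhaseParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative model of one outcome.

    For ``scale="raw"`` values are baseline_mean + subject effect + additive
    group×time effect + residual noise.  For ``scale="log"`` the same model
    holds on the natural-log scale: ``baseline_mean`` is the geometric mean,
    ``baseline_sd`` the geometric SD (> 1), effects are multiplicative
    factors (> 0) and values are log-normal.
    """

    name: str
    scale: str = "raw"
    baseline_mean: float = 0.0
    baseline_sd: float = 1.0
    icc: float = 0.7          # share of baseline variance between subjects
    effects: dict = field(default_factory=dict)  # (group, timepoint) -> shift/factor

    def __post_init__(self):
        if self.scale not in ("raw", "log"):
            raise DesignError(f"unknown scale label {self.scale!r} for outcome {self.name!r}")
        if not 0 <= self.icc <= 1:
            raise DesignError("icc must lie in [0, 1]")
        if self.scale == "log":
            if self.baseline_mean <= 0 or self.baseline_sd <= 1:
                raise DesignError("log outcomes need geometric mean > 0 and geometric SD > 1")
            if any(v <= 0 for v in self.effects.values()):
                raise DesignError("multiplicative effects must be positive")

    @property
    def _mu(self) -> float:
        return np.log(self.baseline_mean) if self.scale == "log" else self.baseline_mean

    @property
    def _sd(self) -> float:
        return np.log(self.baseline_sd) if self.scale == "log" else self.baseline_sd

    @property
    def subject_sd(self) -> float:
        return self._sd * np.sqrt(self.icc)

    @property
    def residual_sd(self) -> float:
        return self._sd * np.sqrt(1.0 - self.icc)

    def effect(self, group: str, timepoint: str) -> float:
        neutral = 1.0 if self.scale == "log" else 0.0
        return self.effects.get((group, timepoint), neutral)


@dataclass(frozen=True)
class StudyDesignConfig:
    """Design of the simulated study."""

    n_per_group: tuple = (13, 11)
    groups: tuple = GROUPS
    timepoints: tuple = TIMEPOINTS
    outcome_specs: dict = field(default_factory=dict)  # name -> OutcomeSpec
    seed: int = 0
    body_mass_mean: float = 84.54
    body_mass_sd: float = 19.17
    pv_intercept_mean: float = 3.0
    pv_intercept_sd: float = 0.22
    pv_slope_mean: float = -0.014
    pv_slope_sd: float = 0.0015
    mpv_offset_mean: float = 1.5   # PV intercept − MPV intercept, m/s
    mpv_offset_sd: float = 0.10
    mpv_slope_mean: float = -0.0075
    mpv_slope_sd: float = 0.0008

    def __post_init__(self):
        if len(self.n_per_group) != len(self.groups):
            raise DesignError("n_per_group and groups must have equal length")
        if any(n < 2 for n in self.n_per_group):
            raise DesignError("each group needs at least 2 subjects")
        if "Pre" not in self.timepoints:
            raise DesignError("the design must include a Pre timepoint")

    def replace(self, **kw) -> "StudyDesignConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# samplers


def _truncated_normal(rng, mean, sd, lower=None, upper=None, size=None):
    """Exact truncated normal; truncation only guards physical ranges."""
    from scipy import stats

    a = -np.inf if lower is None else (lower - mean) / sd
    b = np.inf if upper is None else (upper - mean) / sd
    out = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return float(out) if size is None else out


def simulate_subject_panel(config: StudyDesignConfig, rng=None) -> list[SubjectTruth]:
    """Draw the subject panel (deterministic for a fixed config seed)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    subjects = []
    counter = 0
    for group, n in zip(config.groups, config.n_per_group):
        body_mass = _truncated_normal(rng, config.body_mass_mean, config.body_mass_sd,
                                      lower=45.0, size=n)
        pv_int = _truncated_normal(rng, config.pv_intercept_mean, config.pv_intercept_sd,
                                   lower=1.6, size=n)
        pv_slope = _truncated_normal(rng, config.pv_slope_mean, config.pv_slope_sd,
                                     upper=-0.004, size=n)
        # MPV intercept kept above 1.25 m/s: every athlete in this protocol
        # moves an unloaded bar faster than the 1.2 m/s prescription velocity
        offset = _truncated_normal(rng, config.mpv_offset_mean, config.mpv_offset_sd,
                                   lower=0.2, upper=pv_int - 1.25, size=n)
        mpv_slope = _truncated_normal(rng, config.mpv_slope_mean, config.mpv_slope_sd,
                                      upper=-0.003, size=n)
        baselines = {
            name: spec._mu + rng.normal(0.0, spec.subject_sd, size=n)
            for name, spec in config.outcome_specs.items()
        }
        for i in range(n):
            counter += 1
            subjects.append(
                SubjectTruth(
                    subject_id=f"S{counter:03d}",
                    group=group,
                    body_mass=float(body_mass[i]),
                    true_pv_intercept=float(pv_int[i]),
                    true_pv_slope=float(pv_slope[i]),
                    true_mpv_intercept=float(pv_int[i] - offset[i]),
                    true_mpv_slope=float(mpv_slope[i]),
                    outcome_baselines={name: float(v[i]) for name, v in baselines.items()},
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# jump trace simulator


def simulate_jump_velocity_trace(
    subject: SubjectTruth,
    load: float,
    dt: float = 0.001,
    seed=None,
    noise_sd: float = 0.0,
):
    """Bar-velocity series for one loaded CMJ plus its ground truth.

    The trace is rest → countermovement dip → concentric rise peaking at the
    subject's true PV for this load → post-peak deceleration steeper than
    −9.81 m/s² (ending the propulsive phase at the peak).  The rise exponent
    is calibrated so that applying the propulsive-phase rule to the
    noiseless series returns the subject's true MPV exactly.

    Returns ``(velocity, truth)`` with ``truth = {"pv", "mpv",
    "flight_time"}`` taken from the configured linear profile (never from
    the noisy series).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if load < 0:
        raise ValueError("load must be non-negative")
    pv = subject.true_pv(load)
    mpv = subject.true_mpv(load)
    if pv <= 0 or mpv <= 0:
        raise DesignError(f"load {load} kg exceeds the subject's profile range (PV={pv:.3f}, MPV={mpv:.3f})")
    if mpv >= pv:
        raise DesignError("profile yields MPV ≥ PV; check intercepts/slopes")

    n_rest = int(round(0.20 / dt))
    n_dip = int(round(0.35 / dt))
    n_rise = int(round(0.30 / dt))
    dip = -0.8 * np.sin(np.linspace(0.0, np.pi, n_dip, endpoint=False))
    k = np.arange(1, n_rise + 1) / n_rise

    def build(p):
        rise = pv * k**p
        n_fall = int(round((pv + 0.5) / 20.0 / dt))
        fall = pv - 20.0 * dt * np.arange(1, n_fall + 1)
        return np.concatenate([np.zeros(n_rest), dip, rise, fall, np.zeros(int(round(0.05 / dt)))])

    def measured_mpv(p):
        m, _ = mean_propulsive_velocity(build(p), dt)
        return m

    from scipy.optimize import brentq

    target = mpv
    lo, hi = 1e-3, 30.0
    if not (measured_mpv(hi) < target < measured_mpv(lo)):
        raise DesignError("MPV/PV ratio outside the representable shape family")
    p_star = brentq(lambda p: measured_mpv(p) - target, lo, hi, xtol=1e-10)
    v = build(p_star)
    truth = {"pv": float(pv), "mpv": float(mpv), "flight_time": float(2.0 * pv / 9.81)}
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return v, truth


# ---------------------------------------------------------------------------
# IMU trace simulator


def _smoothstep(x):
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def simulate_imu_repetition(
    params: ThrowPhaseParams,
    dt: float = 0.001,
    seed=None,
):
    """One synthetic throw: ``(ImuTrace, TechniqueLandmarks ground truth)``.

    AccelT (carried on the longitudinal axis) is a 1 G baseline plus three
    Gaussian bumps peaking at the configured phase times with the configured
    amplitudes.  GyroY is flat before onset, then a small fast deviation
    (makes onset detectable within ~1 sample) followed by a logistic rise
    whose inflection sits at ``t_horizontal``.  White Gaussian noise is
    added per channel; the returned ground truth always echoes the
    parameters.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    total_ms = params.onset_time + params.t_impact + params.tail
    n = int(round(total_ms / 1000.0 / dt)) + 1
    t_ms = np.arange(n) * dt * 1000.0
    rel = t_ms - params.onset_time

    accel_x = np.ones(n)
    for t_k, a_k in (
        (params.t_offbalance, params.a_offbalance),
        (params.t_legext, params.a_legext),
        (params.t_impact, params.a_impact),
    ):
        accel_x += (a_k - 1.0) * np.exp(-0.5 * ((rel - t_k) / params.peak_width) ** 2)

    gate = rel >= 0
    step = params.onset_step * _smoothstep(rel / params.onset_step_width)
    sig = 1.0 / (1.0 + np.exp(-(rel - params.t_horizontal) / params.gyro_rise_scale))
    sig0 = 1.0 / (1.0 + np.exp(params.t_horizontal / params.gyro_rise_scale))
    rise = params.gyro_amplitude * np.clip(sig - sig0, 0.0, None)
    gyro_y = np.where(gate, step + rise, 0.0)

    accel = np.column_stack([accel_x, np.zeros(n), np.zeros(n)])
    gyro = np.column_stack([np.zeros(n), gyro_y, np.zeros(n)])
    if params.noise_sd_accel > 0 or params.noise_sd_gyro > 0:
        rng = np.random.default_rng(seed)
        if params.noise_sd_accel > 0:
            accel = accel + rng.normal(0.0, params.noise_sd_accel, size=accel.shape)
        if params.noise_sd_gyro > 0:
            gyro = gyro + rng.normal(0.0, params.noise_sd_gyro, size=gyro.shape)

    trace = ImuTrace(dt=dt, accel=accel, gyro=gyro, meta={"simulated": True})
    truth = TechniqueLandmarks(
        onset_time=params.onset_time,
        tpeak1=params.t_offbalance,
        tpeak2=params.t_legext,
        tpeak3=params.t_impact,
        thor=params.t_horizontal,
        max1=params.a_offbalance,
        max2=params.a_legext,
        max3=params.a_impact,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# study table simulator


def simulate_study(config: StudyDesignConfig):
    """Full study table: ``(StudyDataset, truth)``.

    One row per subject × timepoint × outcome.  Raw outcomes are generated
    additively, log outcomes multiplicatively (log-normal).  ``truth``
    records the subject panel and every injected group×time effect for
    recovery testing.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_panel, rng_study = (np.random.default_rng(s) for s in ss.spawn(2))
    panel = simulate_subject_panel(config, rng=rng_panel)
    rows = []
    for subj in panel:
        for name, spec in config.outcome_specs.items():
            mu_i = subj.outcome_baselines[name]
            for tp in config.timepoints:
                eff = spec.effect(subj.group, tp)
                shift = np.log(eff) if spec.scale == "log" else eff
                if tp == "Pre":
                    shift = 0.0
                val = mu_i + shift + rng_study.normal(0.0, spec.residual_sd)
                if spec.scale == "log":
                    val = np.exp(val)
                rows.append((subj.subject_id, subj.group, tp, name, float(val)))
    frame = pd.DataFrame(rows, columns=["subject", "group", "timepoint", "outcome", "value"])
    scales = {name: spec.scale for name, spec in config.outcome_specs.items()}
    truth = {
        "effects": {
            name: {f"{g}:{tp}": spec.effect(g, tp)
                   for g in config.groups for tp in config.timepoints if tp != "Pre"}
            for name, spec in config.outcome_specs.items()
        },
        "panel": [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "body_mass": s.body_mass,
                "true_pv_intercept": s.true_pv_intercept,
                "true_pv_slope": s.true_pv_slope,
                "true_mpv_intercept": s.true_mpv_intercept,
                "true_mpv_slope": s.true_mpv_slope,
            }
            for s in panel
        ],
        "seed": config.seed,
    }
    return StudyDataset(frame=frame, scales=scales).validate(), truth


# ---------------------------------------------------------------------------
# canonical configurations


def default_study_config(seed: int = 0, n_per_group: tuple = (13, 11)) -> StudyDesignConfig:
    """Study conditions emulating the reference altitude-training design.

    Baseline levels and dispersions follow the reported pre-training
    descriptives; the hypoxia-group effects are the reported adjusted
    between-group differences (additive for raw outcomes, multiplicative for
    the log-normal acceleration magnitudes).
    """
    H = "hypoxia"
    specs = {
        "jump_height_cm": OutcomeSpec(
            "jump_height_cm", "raw", 36.2, 5.5,
            effects={(H, "Post-0"): 3.22, (H, "Post-1"): 1.81, (H, "Post-2"): 2.01},
        ),
        "one_rm_norm": OutcomeSpec(
            "one_rm_norm", "raw", 1.86, 0.28,
            effects={(H, "Post-0"): -0.08, (H, "Post-1"): -0.15, (H, "Post-2"): -0.20},
        ),
        "v0_ms": OutcomeSpec(
            "v0_ms", "raw", 2.97, 0.23,
            effects={(H, "Post-0"): 0.17, (H, "Post-1"): 0.04, (H, "Post-2"): -0.02},
        ),
        "tpeak1_ms": OutcomeSpec(
            "tpeak1_ms", "raw", 390.0, 68.0,
            effects={(H, "Post-0"): 71.0, (H, "Post-1"): 56.0, (H, "Post-2"): 92.0},
        ),
        "tpeak2_ms": OutcomeSpec(
            "tpeak2_ms", "raw", 855.0, 114.0,
            effects={(H, "Post-0"): 132.0, (H, "Post-1"): 115.0, (H, "Post-2"): 142.0},
        ),
        "tpeak3_ms": OutcomeSpec(
            "tpeak3_ms", "raw", 1133.0, 108.0,
            effects={(H, "Post-0"): 113.0, (H, "Post-1"): 134.0, (H, "Post-2"): 159.0},
        ),
        "thor_ms": OutcomeSpec(
            "thor_ms", "raw", 790.0, 128.0,
            effects={(H, "Post-0"): 112.0, (H, "Post-1"): 113.0, (H, "Post-2"): 174.0},
        ),
        "max1_G": OutcomeSpec(
            "max1_G", "log", 6.0, 1.27,
            effects={(H, "Post-0"): 0.96, (H, "Post-1"): 1.06, (H, "Post-2"): 1.08},
        ),
        "max2_G": OutcomeSpec(
            "max2_G", "log", 3.3, 1.33,
            effects={(H, "Post-0"): 0.91, (H, "Post-1"): 0.73, (H, "Post-2"): 0.76},
        ),
        "max3_G": OutcomeSpec(
            "max3_G", "log", 24.0, 1.53,
            effects={(H, "Post-0"): 1.45, (H, "Post-1"): 1.21, (H, "Post-2"): 0.99},
        ),
    }
    return StudyDesignConfig(n_per_group=tuple(n_per_group), outcome_specs=specs, seed=seed)


def null_study_config(
    seed: int = 0,
    n_per_group: tuple = (13, 11),
    outcomes: tuple = ("jump_height_cm",),
) -> StudyDesignConfig:
    """Same conditions with every group×time effect removed (null design)."""
    base = default_study_config(seed=seed, n_per_group=n_per_group)
    specs = {
        name: replace(spec, effects={})
        for name, spec in base.outcome_specs.items()
        if name in outcomes
    }
    missing = set(outcomes) - set(specs)
    if missing:
        raise DesignError(f"unknown outcomes for the null design: {sorted(missing)}")
    return base.replace(outcome_specs=specs)
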