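"""Kinematic landmark extraction for the *ippon-seoi-nage* throw.

A wearable IMU strapped to the thrown dummy records tri-axial acceleration
(G) and angular velocity (rad/s) at a fixed sampling rate (1 kHz by
default).  One throw produces a stereotyped resultant-acceleration (AccelT)
profile with three peaks — off-balance, the judoka's leg extension, and the
dummy's impact on the mat — and a monotone rise of the transversal angular
velocity (GyroY) whose inflection marks the instant the dummy passes through
the horizontal.  This module turns a raw trace into the seven landmark
variables used for analysis: Tpeak1/2/3 and Thor (ms from movement onset)
and Max1/2/3 (G), plus the movement-onset time itself.

Detection rules
---------------
* Onset: first time the transversal angular velocity deviates from its
  pre-trial baseline by more than ``max(onset_threshold_mult × baseline SD,
  onset_floor)`` continuously for at least ``min_sustain`` ms.
* AccelT peaks: local maxima after onset with a minimum prominence and
  mutual separation; the impact peak must be the post-onset global maximum
  and the two preceding peaks are taken in temporal order.
* Thor: steepest-rise inflection (downward zero-crossing of the second
  derivative at the largest first derivative) of the min–max normalized,
  low-pass-filtered GyroY after onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import LandmarkNotFoundError, NoOnsetError

__all__ = [
    "ImuTrace",
    "DetectorConfig",
    "TechniqueLandmarks",
    "resultant_magnitude",
    "detect_onset",
    "detect_accel_peaks",
    "detect_horizontal_position",
    "extract_landmarks",
    "select_technique_repetition",
    "cronbach_alpha",
    "landmarks_to_frame",
]

_TRACE_COLUMNS = [
    "t_s",
    "accel_x_G",
    "accel_y_G",
    "accel_z_G",
    "gyro_x_rads",
    "gyro_y_rads",
    "gyro_z_rads",
]


@dataclass
class ImuTrace:
    """Synchronized tri-axial accelerometer + gyroscope recording.

    ``accel`` and ``gyro`` are ``(n, 3)`` arrays (columns x = longitudinal,
    y = transversal, z = anterior–posterior) in G and rad/s respectively,
    sampled every ``dt`` seconds.
    """

    dt: float
    accel: np.ndarray
    gyro: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValueError("accel and gyro must both be (n, 3) arrays of equal length")
        if self.accel.shape[0] < 2:
            raise ValueError("trace must contain at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def accel_t(self) -> np.ndarray:
        """Resultant acceleration AccelT (G)."""
        return resultant_magnitude(self.accel[:, 0], self.accel[:, 1], self.accel[:, 2])

    @property
    def gyro_t(self) -> np.ndarray:
        """Resultant angular velocity GyroT (rad/s)."""
        return resultant_magnitude(self.gyro[:, 0], self.gyro[:, 1], self.gyro[:, 2])

    @property
    def gyro_y(self) -> np.ndarray:
        return self.gyro[:, 1]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) * self.dt
        return pd.DataFrame(
            np.column_stack([t, self.accel, self.gyro]), columns=_TRACE_COLUMNS
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "ImuTrace":
        df = pd.read_csv(path)
        missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"IMU trace CSV {path} is missing columns: {missing}")
        t = df["t_s"].to_numpy()
        dt = float(np.median(np.diff(t)))
        accel = df[_TRACE_COLUMNS[1:4]].to_numpy()
        gyro = df[_TRACE_COLUMNS[4:7]].to_numpy()
        return cls(dt=dt, accel=accel, gyro=gyro, meta=dict(meta or {}))


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable constants of the landmark detectors.

    Only the 50 ms sustain rule is dictated by the measurement protocol;
    the remaining values are detector choices, all in physical units.
    """

    baseline_window: float = 200.0      # ms of pre-trial rest used as baseline
    onset_threshold_mult: float = 3.0   # multiples of baseline SD
    onset_floor: float = 0.1            # rad/s, lower bound on the threshold
    min_sustain: float = 50.0           # ms the deviation must persist
    smoothing_cutoff: float = 10.0      # Hz low-pass for the GyroY inflection
    min_peak_prominence: float = 0.3    # G (well above smoothed-noise prominences)
    min_peak_separation: float = 100.0  # ms
    accel_lowpass: float = 30.0         # Hz low-pass before AccelT peak picking
    edge_guard: float = 150.0           # ms excluded at segment edges (filter rim)

    def __post_init__(self):
        if self.min_sustain <= 0 or self.baseline_window <= 0 or self.smoothing_cutoff <= 0:
            raise ValueError("min_sustain, baseline_window and smoothing_cutoff must be positive")

    def replace(self, **kw) -> "DetectorConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class TechniqueLandmarks:
    """Landmark set of one throw: onset absolute, everything else from onset."""

    onset_time: float  # ms, absolute within the recording
    tpeak1: float      # ms from onset
    tpeak2: float
    tpeak3: float
    thor: float        # ms from onset
    max1: float        # G
    max2: float
    max3: float

    def validate(self) -> "TechniqueLandmarks":
        if not (0 < self.tpeak1 < self.tpeak2 < self.tpeak3):
            raise LandmarkNotFoundError(
                f"peak times are not strictly ordered: {self.tpeak1}, {self.tpeak2}, {self.tpeak3}",
                stage="ordering",
            )
        if not (0 < self.thor < self.tpeak3):
            raise LandmarkNotFoundError(
                f"Thor ({self.thor} ms) must fall between onset and the impact peak ({self.tpeak3} ms)",
                stage="ordering",
            )
        if min(self.max1, self.max2, self.max3) <= 0:
            raise LandmarkNotFoundError("peak magnitudes must be positive", stage="ordering")
        return self


def resultant_magnitude(x, y, z) -> np.ndarray:
    """Element-wise Euclidean norm of three equal-length series."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("the three component series must have equal length")
    return np.sqrt(x * x + y * y + z * z)


def _lowpass(series: np.ndarray, dt: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass; identity on traces too short to filter."""
    nyq = 0.5 / dt
    if cutoff >= nyq:
        return np.asarray(series, dtype=float)
    sos = signal.butter(order, cutoff / nyq, btype="low", output="sos")
    padlen = 3 * (2 * order + 1)
    if len(series) <= padlen + 1:
        return np.asarray(series, dtype=float)
    return signal.sosfiltfilt(sos, series)


def detect_onset(gyro_y, dt: float, cfg: DetectorConfig = DetectorConfig()) -> float:
    """Movement onset (ms): first sustained deviation of GyroY from baseline.

    The baseline mean and SD are taken over the first ``cfg.baseline_window``
    ms (pre-trial rest).  A sample qualifies when its absolute deviation
    exceeds ``max(onset_threshold_mult × baseline SD, onset_floor)``; onset is
    the first sample opening an uninterrupted run of at least
    ``cfg.min_sustain`` ms of qualifying samples.
    """
    g = np.asarray(gyro_y, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_base = max(2, int(round(cfg.baseline_window / 1000.0 / dt)))
    n_sus = max(1, int(round(cfg.min_sustain / 1000.0 / dt)))
    if len(g) <= n_base + n_sus:
        raise ValueError(
            f"series of {len(g)} samples is too short for a {cfg.baseline_window} ms baseline "
            f"plus {cfg.min_sustain} ms sustain"
        )
    base = g[:n_base]
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    thr = max(cfg.onset_threshold_mult * sd, cfg.onset_floor)
    dev = np.abs(g - mu) > thr
    if not dev.any():
        raise NoOnsetError("no deviation from baseline exceeds the threshold")
    # length of the qualifying run starting at each sample
    run = np.zeros(len(dev) + 1, dtype=int)
    for i in range(len(dev) - 1, -1, -1):
        run[i] = run[i + 1] + 1 if dev[i] else 0
    hits = np.nonzero(run[:-1] >= n_sus)[0]
    if hits.size == 0:
        raise NoOnsetError(
            f"deviations never persist for {cfg.min_sustain} ms (min_sustain rule)"
        )
    return float(hits[0] * dt * 1000.0)


def detect_accel_peaks(
    accel_t,
    dt: float,
    onset_time: float,
    cfg: DetectorConfig = DetectorConfig(),
) -> list[tuple[float, float]]:
    """The three AccelT peaks after onset: [(ms from onset, G), ...].

    Peaks are local maxima of the lightly low-pass-filtered resultant
    acceleration with prominence ≥ ``min_peak_prominence`` and pairwise
    separation ≥ ``min_peak_separation``.  The impact peak is required to be
    the post-onset global maximum; the off-balance and leg-extension peaks
    are the two most prominent maxima preceding it, reported in temporal
    order.  Raises :class:`LandmarkNotFoundError` (with the count found)
    when fewer than three maxima qualify.
    """
    a = np.asarray(accel_t, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    i0 = int(round(onset_time / 1000.0 / dt))
    if i0 < 0 or i0 >= len(a) - 2:
        raise ValueError("onset lies outside the trace")
    sm = _lowpass(a, dt, cfg.accel_lowpass)
    dist = max(1, int(round(cfg.min_peak_separation / 1000.0 / dt)))
    idx, props = signal.find_peaks(sm[i0:], prominence=cfg.min_peak_prominence, distance=dist)
    if idx.size < 3:
        raise LandmarkNotFoundError(
            f"found only {idx.size} qualifying AccelT peaks (3 required)",
            found=int(idx.size),
            stage="peaks",
        )
    heights = sm[i0 + idx]
    impact_pos = int(np.argmax(heights))
    before = np.arange(impact_pos)
    if before.size < 2:
        raise LandmarkNotFoundError(
            f"only {before.size + 1} peaks up to the impact peak (3 required)",
            found=int(before.size + 1),
            stage="peaks",
        )
    # two most prominent pre-impact peaks, then temporal order
    prom = props["prominences"][before]
    keep = before[np.argsort(prom)[-2:]]
    chosen = np.sort(np.append(keep, impact_pos))
    out = []
    for k in chosen:
        t_ms = (i0 + idx[k]) * dt * 1000.0 - onset_time
        out.append((float(t_ms), float(sm[i0 + idx[k]])))
    return out


def detect_horizontal_position(
    gyro_y,
    dt: float,
    onset_time: float,
    cfg: DetectorConfig = DetectorConfig(),
) -> float:
    """Thor (ms from onset): steepest-rise inflection of normalized GyroY.

    GyroY over [onset, end] is min–max normalized to [0, 1], low-pass
    filtered at ``cfg.smoothing_cutoff``, and differentiated; Thor is the
    downward zero-crossing of the second derivative (a local maximum of the
    first derivative) with the largest first derivative — the inflection of
    the main rise toward the dummy's horizontal position.
    """
    g = np.asarray(gyro_y, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    i0 = int(round(onset_time / 1000.0 / dt))
    seg = g[i0:]
    if seg.size < 10:
        raise ValueError("too few samples after onset")
    lo, hi = float(seg.min()), float(seg.max())
    if hi <= lo:
        raise LandmarkNotFoundError("GyroY is constant after onset", stage="inflection")
    norm = (seg - lo) / (hi - lo)
    sm = _lowpass(norm, dt, cfg.smoothing_cutoff)
    d1 = np.gradient(sm, dt)
    d2 = np.gradient(d1, dt)
    guard = max(2, int(round(cfg.edge_guard / 1000.0 / dt)))
    span = np.arange(guard, len(sm) - guard - 1)
    if span.size < 2:
        raise LandmarkNotFoundError("segment too short after edge guard", stage="inflection")
    # a real inflection needs the slope to vary; a (numerically) linear rise
    # has none even though round-off can fabricate curvature zero-crossings
    d1_span = d1[span]
    d1_range = float(d1_span.max() - d1_span.min())
    if d1_range <= 0.05 * max(abs(float(d1_span.max())), 1e-12):
        raise LandmarkNotFoundError(
            "first derivative is constant over the segment (no inflection)",
            stage="inflection",
        )
    down = span[(d2[span] > 0) & (d2[span + 1] <= 0)]
    if down.size == 0:
        raise LandmarkNotFoundError(
            "no downward zero-crossing of the second derivative (no steepest-rise inflection)",
            stage="inflection",
        )
    j = down[int(np.argmax(d1[down]))]
    # sub-sample refinement: linear interpolation of d2 across the crossing
    denom = d2[j] - d2[j + 1]
    frac = float(d2[j] / denom) if denom > 0 else 0.0
    thor = (j + frac) * dt * 1000.0
    if thor <= 0:
        raise LandmarkNotFoundError("inflection found at or before onset", stage="inflection")
    return float(thor)


def extract_landmarks(trace: ImuTrace, cfg: DetectorConfig = DetectorConfig()) -> TechniqueLandmarks:
    """Full landmark extraction for one repetition.

    Composes onset detection (GyroY), AccelT peak picking and the Thor
    inflection; the result satisfies the landmark ordering invariants or an
    error tagged with the failing stage is raised.
    """
    try:
        onset = detect_onset(trace.gyro_y, trace.dt, cfg)
    except NoOnsetError:
        raise
    peaks = detect_accel_peaks(trace.accel_t, trace.dt, onset, cfg)
    thor = detect_horizontal_position(trace.gyro_y, trace.dt, onset, cfg)
    (t1, m1), (t2, m2), (t3, m3) = peaks
    return TechniqueLandmarks(
        onset_time=onset, tpeak1=t1, tpeak2=t2, tpeak3=t3,
        thor=thor, max1=m1, max2=m2, max3=m3,
    ).validate()


def select_technique_repetition(reps) -> int:
    """Index of the repetition kept for analysis.

    ``reps`` is a sequence of ``(TechniqueLandmarks, rating)`` pairs.  The
    single worst-rated repetition is excluded (rating ties broken by
    excluding the slowest Thor); among the remainder the repetition with the
    quickest time to the dummy's horizontal position is chosen.
    """
    reps = list(reps)
    if len(reps) < 2:
        raise ValueError("at least two rated repetitions are required")
    ratings = [float(r) for _, r in reps]
    thors = [lm.thor for lm, _ in reps]
    worst_rating = min(ratings)
    worst_candidates = [i for i, r in enumerate(ratings) if r == worst_rating]
    excluded = max(worst_candidates, key=lambda i: thors[i])
    remaining = [i for i in range(len(reps)) if i != excluded]
    return min(remaining, key=lambda i: thors[i])


def cronbach_alpha(ratings) -> float:
    """Cronbach's alpha for interrater reliability, raters as scale items.

    ``ratings`` is a (raters × items) matrix; alpha = k/(k−1) ×
    (1 − Σ rater variances / variance of the rater-sum score), with
    sample (n−1) variances.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("ratings must be a matrix with ≥ 2 raters and ≥ 2 items")
    k = R.shape[0]
    item_vars = R.var(axis=1, ddof=1)
    total_var = R.sum(axis=0).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha is undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def landmarks_to_frame(records) -> pd.DataFrame:
    """Long landmark records → the landmarks CSV layout (ms and G)."""
    rows = []
    for meta, lm in records:
        row = dict(meta)
        row.update(
            Tpeak1_accelT=lm.tpeak1,
            Tpeak2_accelT=lm.tpeak2,
            Tpeak3_accelT=lm.tpeak3,
            Thor=lm.thor,
            Max1_accelT=lm.max1,
            Max2_accelT=lm.max2,
            Max3_accelT=lm.max3,
        )
        rows.append(row)
    return pd.DataFrame(rows)
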