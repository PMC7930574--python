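"""Loaded countermovement-jump (CMJ) mechanics and load-velocity profiling.

A linear transducer attached to the bar of a Smith machine records bar
velocity at 1 kHz during CMJs with increasing loads.  From each trial we
take the peak velocity (PV) and the mean propulsive velocity (MPV, the mean
over the propulsive phase: the concentric portion where acceleration stays
at or above −9.81 m/s²).  Per athlete, first-order polynomials fitted to
(load, PV) and (load, MPV) points give the individual load-velocity
relationship, from which are derived:

* 1RM — the load whose predicted MPV is 0.33 m/s (and its body-mass
  normalized value),
* V0 (velocity intercept), L0 (load intercept) and the profile slope
  −L0/V0,
* PV at 25/50/75/100 % of body mass,
* the velocity-based training load, e.g. the load linked to an MPV of
  1.2 m/s, re-fitted weekly from a short incremental test.

Jump height of the unloaded CMJ is estimated from flight time as
h = g·t²/8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .errors import FitError, NoConcentricPhaseError, ProfileError

G_MS2 = 9.81  # acceleration due to gravity, m/s²; also the propulsive-phase cutoff

__all__ = [
    "JumpTrial",
    "LinearFit",
    "LoadVelocityProfile",
    "mean_propulsive_velocity",
    "smooth_velocity",
    "fit_load_velocity",
    "derive_profile",
    "load_at_velocity",
    "jump_height_from_flight_time",
    "select_best_jump",
]


@dataclass
class JumpTrial:
    """One CMJ repetition: load on the bar plus measured outputs."""

    load: float                      # kg (0 for the unloaded jump)
    pv: float | None = None          # m/s
    mpv: float | None = None         # m/s
    flight_time: float | None = None  # s, unloaded jumps only
    velocity_trace: np.ndarray | None = None
    dt: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.load < 0:
            raise ValueError("load must be non-negative")
        if self.pv is not None and self.mpv is not None and not (self.pv >= self.mpv > 0):
            raise ValueError("expected pv ≥ mpv > 0")

    @property
    def jump_height_cm(self) -> float | None:
        if self.flight_time is None:
            return None
        return jump_height_from_flight_time(self.flight_time)


@dataclass(frozen=True)
class LinearFit:
    """First-order polynomial v = intercept + slope·load."""

    intercept: float       # m/s
    slope: float           # (m/s)/kg
    r_squared: float
    n_points: int
    positive_slope: bool = False  # flagged, not fatal: profile is unusable downstream

    def predict(self, load) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(load, dtype=float)

    def inverse(self, velocity: float) -> float:
        return (velocity - self.intercept) / self.slope


@dataclass(frozen=True)
class LoadVelocityProfile:
    body_mass: float            # kg
    pv_fit: LinearFit
    mpv_fit: LinearFit
    one_rm: float               # kg, load at MPV = 0.33 m/s
    one_rm_norm: float          # kg per kg body mass
    v0: float                   # m/s, velocity intercept of the source fit
    l0: float                   # kg, load intercept of the source fit
    slope_param: float          # kg·s/m, −L0/V0
    pv_at_bm: dict              # {25, 50, 75, 100} (% body mass) -> m/s
    source_fit: str = "pv"
    extrapolated: bool = False  # 1RM/pv_at_bm beyond the tested load range


def smooth_velocity(velocity_trace, dt: float, cutoff: float) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a bar-velocity trace."""
    v = np.asarray(velocity_trace, dtype=float)
    nyq = 0.5 / dt
    if cutoff >= nyq:
        return v
    sos = signal.butter(4, cutoff / nyq, btype="low", output="sos")
    if v.size <= 28:  # shorter than the filter's padding requirement
        return v
    return signal.sosfiltfilt(sos, v)


def mean_propulsive_velocity(velocity_trace, dt: float, smooth_cutoff: float | None = None):
    """MPV (m/s) and the propulsive-segment bounds ``(start, end)``.

    The concentric phase is the positive-velocity stretch containing the
    velocity peak: it starts at the upward zero-crossing preceding the peak
    and ends when velocity returns to zero after it.  The propulsive phase
    ends earlier at the first sample whose finite-difference (central)
    acceleration drops below −9.81 m/s²; the bounds are half-open
    ``[start, end)`` sample indices.

    ``smooth_cutoff`` (Hz) optionally low-pass filters the trace before
    segmentation and averaging — necessary on noisy recordings, where raw
    sample-to-sample differentiation at 1 kHz is noise-dominated.
    """
    v = np.asarray(velocity_trace, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if v.size < 2:
        raise ValueError("velocity trace must contain at least 2 samples")
    if smooth_cutoff is not None:
        v = smooth_velocity(v, dt, smooth_cutoff)
    if not (v > 0).any():
        raise NoConcentricPhaseError("no positive velocity: trace has no concentric phase")
    imax = int(np.argmax(v))
    nonpos = np.nonzero(v[: imax + 1] <= 0)[0]
    start = int(nonpos[-1] + 1) if nonpos.size else 0
    after = np.nonzero(v[imax:] <= 0)[0]
    conc_end = int(imax + after[0]) if after.size else int(v.size)
    # central-difference acceleration (one-sided at the ends)
    a = np.gradient(v, dt)
    viol = np.nonzero(a[start:conc_end] < -G_MS2)[0]
    end = int(start + viol[0]) if viol.size else conc_end
    if end <= start:
        end = start + 1
    return float(v[start:end].mean()), (start, end)


def fit_load_velocity(points) -> LinearFit:
    """Ordinary least squares line through (load kg, velocity m/s) points."""
    pts = [(float(l), float(v)) for l, v in points]
    loads = np.array([p[0] for p in pts])
    vels = np.array([p[1] for p in pts])
    if np.unique(loads).size < 2:
        raise FitError("at least two distinct loads are required for a load-velocity fit")
    res = stats.linregress(loads, vels)
    positive = res.slope >= 0
    if positive:
        warnings.warn("load-velocity fit has a non-negative slope; profile quantities are unreliable")
    return LinearFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=len(pts),
        positive_slope=bool(positive),
    )


def load_at_velocity(fit: LinearFit, v_target: float) -> float:
    """Load (kg) at which the fitted line predicts ``v_target``.

    Used for the 1RM (MPV = 0.33 m/s) and for the weekly velocity-based
    training-load prescription (MPV = 1.2 m/s) from a fresh incremental-test
    fit.
    """
    if fit.slope >= 0:
        raise ProfileError("load_at_velocity requires a negative-slope fit")
    if v_target > fit.intercept:
        raise ProfileError(
            f"target velocity {v_target} m/s exceeds the fit intercept {fit.intercept} m/s "
            "(implied load is negative)"
        )
    return float(fit.inverse(v_target))


def derive_profile(
    pv_fit: LinearFit,
    mpv_fit: LinearFit,
    body_mass: float,
    source_fit: str = "pv",
    one_rm_velocity: float = 0.33,
    max_tested_load: float | None = None,
) -> LoadVelocityProfile:
    """All derived load-velocity quantities for one athlete.

    V0/L0/slope come from the ``source_fit`` line (peak velocity by default;
    its intercepts match the magnitudes the profile variables are meant to
    carry, e.g. slope ≈ −V0-to-L0 ratio around −70 kg·s/m); the 1RM always
    solves the MPV line at ``one_rm_velocity``.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    for name, f in (("pv", pv_fit), ("mpv", mpv_fit)):
        if f.slope >= 0:
            raise ProfileError(f"{name} fit must have a negative slope")
    one_rm = load_at_velocity(mpv_fit, one_rm_velocity)
    if one_rm < 0:
        raise ProfileError("1RM extrapolation yields a negative load")
    src = {"pv": pv_fit, "mpv": mpv_fit}.get(source_fit)
    if src is None:
        raise ValueError("source_fit must be 'pv' or 'mpv'")
    v0 = src.intercept
    l0 = -src.intercept / src.slope
    slope_param = -l0 / v0  # algebraically 1/src.slope
    fractions = (25, 50, 75, 100)
    pv_at_bm = {f: float(pv_fit.predict(body_mass * f / 100.0)) for f in fractions}
    extrapolated = False
    if max_tested_load is not None:
        extrapolated = one_rm > max_tested_load or body_mass > max_tested_load
    return LoadVelocityProfile(
        body_mass=float(body_mass),
        pv_fit=pv_fit,
        mpv_fit=mpv_fit,
        one_rm=float(one_rm),
        one_rm_norm=float(one_rm / body_mass),
        v0=float(v0),
        l0=float(l0),
        slope_param=float(slope_param),
        pv_at_bm=pv_at_bm,
        source_fit=source_fit,
        extrapolated=extrapolated,
    )


def jump_height_from_flight_time(t_flight: float) -> float:
    """Jump height (cm) from flight time (s): h = g·t²/8."""
    if t_flight < 0:
        raise ValueError("flight time must be non-negative")
    return 100.0 * G_MS2 * t_flight**2 / 8.0


def select_best_jump(trials, per_load: bool = True):
    """Best repetition(s): highest PV per load, or the highest unloaded jump.

    With ``per_load=True`` returns ``{load: JumpTrial}`` keeping the max-PV
    trial of each load; otherwise returns the single trial with the greatest
    jump height (from flight time).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials supplied")
    if per_load:
        best: dict[float, JumpTrial] = {}
        for tr in trials:
            if tr.pv is None:
                raise ValueError("per-load selection requires pv on every trial")
            cur = best.get(tr.load)
            if cur is None or tr.pv > cur.pv:
                best[tr.load] = tr
        return best
    heights = []
    for tr in trials:
        h = tr.jump_height_cm
        if h is None:
            raise ValueError("unloaded-jump selection requires flight_time on every trial")
        heights.append(h)
    return trials[int(np.argmax(heights))]
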