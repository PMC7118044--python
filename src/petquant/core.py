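"""Core data structures and the forward kinetic model.

Time conventions: frame schedules are stored in seconds (acquisition
convention); all kinetic rate constants are per minute and continuous-time
curves are evaluated on a time axis in minutes. Activity concentrations are
kBq/cm^3 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

__all__ = [
    "DynamicImage",
    "LabelAtlas",
    "FrameSchedule",
    "study_frame_schedule",
    "InputFunctionParams",
    "input_function",
    "KineticParams",
    "TimeActivityCurve",
    "fine_time_grid",
    "tissue_curve_2tcm",
    "one_tissue_curve",
    "frame_average",
    "FINE_DT_S",
]

#: resolution of the continuous simulation grid, seconds
FINE_DT_S = 1.0

#: FWHM of a Gaussian in units of its standard deviation
FWHM_PER_SIGMA = 2.354820045030949


class ConfigurationError(ValueError):
    """Invalid model or acquisition configuration."""


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition, in seconds.

    Frames must be contiguous and non-overlapping with positive durations.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ConfigurationError("frame_start and frame_duration must be 1-D and aligned")
        if np.any(dur <= 0):
            raise ConfigurationError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ConfigurationError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def total_seconds(self) -> float:
        return float(self.frame_end[-1] - self.frame_start[0])

    @property
    def mid_minutes(self) -> np.ndarray:
        """Frame midpoints in minutes, the time base of frame-domain fits."""
        return (self.frame_start + 0.5 * self.frame_duration) / 60.0

    @property
    def duration_minutes(self) -> np.ndarray:
        return self.frame_duration / 60.0


def study_frame_schedule() -> FrameSchedule:
    """The 39-frame, 90-minute dynamic schedule used throughout.

    12 x 10 s, 3 x 20 s, 3 x 30 s, 3 x 60 s, 3 x 150 s and 15 x 300 s,
    totalling 5400 s.
    """
    dur = np.array([10.0] * 12 + [20.0] * 3 + [30.0] * 3 + [60.0] * 3 + [150.0] * 3 + [300.0] * 15)
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur)


def fine_time_grid(schedule: FrameSchedule) -> np.ndarray:
    """Uniform 1-s simulation grid spanning the schedule, in minutes."""
    n = int(round(schedule.total_seconds / FINE_DT_S))
    return np.arange(n + 1) * (FINE_DT_S / 60.0)


# ---------------------------------------------------------------------------
# Input function (tri-exponential bolus with appearance delay)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputFunctionParams:
    """Feng-type tri-exponential bolus plasma curve.

    ``A1`` is the slope of the initial linear rise (kBq mL^-1 min^-1); ``A2``
    and ``A3`` (kBq/mL) scale the two washout exponentials; ``lambda1 >
    lambda2 > lambda3 > 0`` (min^-1); ``t0`` is the tracer appearance delay
    in minutes. The curve is identically zero for ``t <= t0``, continuous at
    ``t0`` and non-negative everywhere.
    """

    A1: float = 300.0
    A2: float = 6.0
    A3: float = 1.0
    lambda1: float = 4.0
    lambda2: float = 0.5
    lambda3: float = 0.008
    t0: float = 0.5

    def __post_init__(self):
        if not (self.lambda1 > self.lambda2 > self.lambda3 > 0):
            raise ConfigurationError("require lambda1 > lambda2 > lambda3 > 0")
        if min(self.A1, self.A2, self.A3) < 0 or self.t0 < 0:
            raise ConfigurationError("amplitudes and t0 must be non-negative")


def input_function(params: InputFunctionParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the bolus input at times ``t`` (minutes, sorted, >= 0)."""
    t = np.asarray(t, dtype=float)
    tp = t - params.t0
    with np.errstate(over="ignore"):
        c = (
            (params.A1 * tp - params.A2 - params.A3) * np.exp(-params.lambda1 * tp)
            + params.A2 * np.exp(-params.lambda2 * tp)
            + params.A3 * np.exp(-params.lambda3 * tp)
        )
    return np.where(tp > 0, c, 0.0)


# ---------------------------------------------------------------------------
# Two-tissue compartment model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """2TCM micro-parameters.

    ``K1`` (mL cm^-3 min^-1) and ``k2`` (min^-1) describe exchange between
    plasma and the free/non-displaceable compartment; ``k3``/``k4`` (min^-1)
    exchange with the specifically bound compartment; ``V_B`` is the
    fractional blood volume. The macro-parameter is
    ``V_T = (K1/k2) * (1 + k3/k4)``.
    """

    K1: float
    k2: float
    k3: float
    k4: float
    V_B: float = 0.036

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3, self.k4) <= 0:
            raise ConfigurationError("all rate constants must be positive")
        if not (0.0 <= self.V_B <= 0.2):
            raise ConfigurationError("V_B must lie in [0, 0.2]")

    @property
    def vt(self) -> float:
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)


def _exp_conv(theta: float, t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """``int_0^t exp(-theta (t-s)) c(s) ds`` for piecewise-linear ``c``.

    Exact for a linear interpolant of ``c`` on the uniform grid ``t``;
    evaluated by the equivalent first-order recursion (O(n)).
    """
    dt = t[1] - t[0]
    if theta * dt < 1e-12:
        return cumulative_trapezoid(c, t, initial=0.0)
    e = np.exp(-theta * dt)
    i0 = (1.0 - e) / theta
    i1 = 1.0 / theta - i0 / (theta * dt)
    # y_i = e*y_{i-1} + (i0-i1)*c_{i-1} + i1*c_i, y_0 = 0
    y = lfilter([i1, i0 - i1], [1.0, -e], c)
    if c[0] != 0.0:
        y = y - i1 * c[0] * e ** np.arange(t.size)
    return y


def tissue_curve_2tcm(
    kp: KineticParams,
    cp: np.ndarray,
    t: np.ndarray,
    blood: np.ndarray | None = None,
) -> np.ndarray:
    """Continuous 2TCM tissue curve on the uniform grid ``t`` (minutes).

    Solves the standard linear two-compartment system driven by the plasma
    input ``cp`` via its analytic bi-exponential impulse response, and mixes
    in the whole-blood signal: ``(1 - V_B) * (C1 + C2) + V_B * C_b``. With
    no radiometabolite or plasma/whole-blood correction, ``blood`` defaults
    to ``cp`` itself.
    """
    cp = np.asarray(cp, dtype=float)
    s = kp.k2 + kp.k3 + kp.k4
    disc = np.sqrt(max(s * s - 4.0 * kp.k2 * kp.k4, 0.0))
    th1 = 0.5 * (s + disc)
    th2 = 0.5 * (s - disc)
    if th1 - th2 < 1e-6 * th1:
        # near-equal eigenvalues (k2+k3 ~ k4 with tiny k3*k4): evaluate the
        # smooth limit by a symmetric split; relative error O(1e-12)
        eps = 5e-7 * th1
        th1, th2 = th1 + eps, th2 - eps
    a = kp.k3 + kp.k4
    x1 = _exp_conv(th1, t, cp)
    x2 = _exp_conv(th2, t, cp)
    ct = kp.K1 / (th1 - th2) * ((th1 - a) * x1 + (a - th2) * x2)
    cb = cp if blood is None else np.asarray(blood, dtype=float)
    return (1.0 - kp.V_B) * ct + kp.V_B * cb


def one_tissue_curve(K1: float, k2: float, cp: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Single-compartment tissue curve ``K1 * exp(-k2 t) (x) cp`` (no blood term)."""
    return K1 * _exp_conv(k2, t, np.asarray(cp, dtype=float))


# ---------------------------------------------------------------------------
# Time-activity curves and frame averaging
# ---------------------------------------------------------------------------

@dataclass
class TimeActivityCurve:
    """Frame-resolved activity concentration for one region or the blood pool."""

    schedule: FrameSchedule
    activity: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ConfigurationError("activity length must equal the frame count")

    def with_activity(self, activity: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, activity, self.label)


@dataclass
class DynamicImage:
    """4D dynamic PET volume (x, y, z, frame) in kBq/cm^3 with frame timing."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: float = 0.776

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[3] != self.schedule.n_frames:
            raise ConfigurationError("data must be 4-D with frame axis matching the schedule")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelAtlas:
    """Integer region labels on the image grid; 0 is background."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or np.any(self.labels < 0):
            raise ConfigurationError("labels must be a 3-D non-negative integer array")

    def mask(self, region: str | int) -> np.ndarray:
        if isinstance(region, str):
            match = [k for k, v in self.names.items() if v == region]
            if not match:
                raise KeyError(f"unknown region {region!r}")
            region = match[0]
        m = self.labels == region
        if not m.any():
            raise KeyError(f"label {region} not present in atlas")
        return m

    @property
    def regions(self) -> list[str]:
        present = np.unique(self.labels)
        return [self.names.get(k, str(k)) for k in present if k != 0]


def frame_average(curve: np.ndarray, t: np.ndarray, schedule: FrameSchedule,
                  label: str = "") -> TimeActivityCurve:
    """Average a continuous curve over each frame interval.

    ``curve`` is sampled on the uniform minute grid ``t``, which must span
    the schedule. Each frame value is the trapezoid time-average of the
    curve over [frame_start, frame_end].
    """
    t = np.asarray(t, dtype=float)
    start_min = schedule.frame_start / 60.0
    end_min = schedule.frame_end / 60.0
    if start_min[0] < t[0] - 1e-9 or end_min[-1] > t[-1] + 1e-9:
        raise ConfigurationError("schedule extends beyond the simulated grid")
    integral = cumulative_trapezoid(curve, t, initial=0.0)
    num = np.interp(end_min, t, integral) - np.interp(start_min, t, integral)
    return TimeActivityCurve(schedule, num / (end_min - start_min), label)
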