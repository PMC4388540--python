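"""Frame schedules, time-activity curves, and compartment-model forward solutions.

All times are in minutes.  Activity units are arbitrary but must be
consistent across every curve in an analysis.  Curves are defined at frame
midpoints; time integrals prepend a node at (0, 0), the standard
dynamic-PET convention for decay-corrected bolus data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.signal import lfilter

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "Kinetics2TC",
    "LoganResult",
    "trapz_integral",
    "finite_diff_derivative",
    "forward_2tc",
    "forward_1tc",
    "read_tacs_csv",
    "write_tacs_csv",
]

#: Recognized curve roles.
ROLES = frozenset(
    {
        "tissue",
        "reference",
        "arterial_roi",
        "background",
        "plasma",
        "whole_blood",
        "rate",
    }
)

#: Roles that must be non-negative everywhere.
_NONNEG_ROLES = frozenset({"plasma", "whole_blood"})


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame grid: per-frame start and duration in minutes.

    Frames must be non-overlapping and ordered; midpoints (start + half
    duration) form the time axis on which every curve is sampled.
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or duration.shape != start.shape:
            raise ValueError("start and duration must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if not np.all(duration > 0):
            raise ValueError("frame durations must be positive")
        if not np.all(np.diff(start) > 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = start + duration
        if np.any(start[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        if not np.all(np.diff(self.midpoint) > 0):
            raise ValueError("frame midpoints must be strictly increasing")

    @property
    def midpoint(self) -> np.ndarray:
        return self.start + 0.5 * self.duration

    @property
    def end(self) -> np.ndarray:
        """Per-frame end times."""
        return self.start + self.duration

    @property
    def F(self) -> int:
        return int(self.start.size)

    @property
    def span(self) -> float:
        """Total protocol end time in minutes."""
        return float(self.end[-1])

    @classmethod
    def from_groups(cls, groups: Sequence[tuple[int, float]]) -> "FrameSchedule":
        """Build a schedule from (count, duration_minutes) groups."""
        durations = []
        for count, dur in groups:
            if count <= 0 or dur <= 0:
                raise ValueError("frame group counts and durations must be positive")
            durations.extend([float(dur)] * int(count))
        duration = np.asarray(durations)
        start = np.concatenate([[0.0], np.cumsum(duration)[:-1]])
        return cls(start=start, duration=duration)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start, other.start) and np.array_equal(
            self.duration, other.duration
        )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration per frame, tagged with a role label."""

    schedule: FrameSchedule
    values: np.ndarray
    role: str = "tissue"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.F,):
            raise ValueError(
                f"expected {self.schedule.F} values, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("curve values must be finite")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        if self.role in _NONNEG_ROLES and np.any(values < 0):
            raise ValueError(f"{self.role} curves must be non-negative")

    @property
    def midpoint(self) -> np.ndarray:
        return self.schedule.midpoint

    def with_values(self, values: np.ndarray, role: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, values, role or self.role)


@dataclass(frozen=True)
class Kinetics2TC:
    """Two-tissue-compartment rate constants.

    K1 is the plasma-to-tissue influx rate (mL·cm⁻³·min⁻¹ by convention);
    k2, k3, k4 are first-order rate constants (min⁻¹).
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def _alphas(self) -> tuple[float, float]:
        b = self.k2 + self.k3 + self.k4
        disc = b * b - 4.0 * self.k2 * self.k4
        # Non-negative rates cannot give a negative discriminant:
        # b^2 - 4 k2 k4 >= (k2 + k4)^2 - 4 k2 k4 = (k2 - k4)^2 >= 0.
        assert disc >= -1e-12 * max(b * b, 1.0)
        root = math.sqrt(max(disc, 0.0))
        return (0.5 * (b - root), 0.5 * (b + root))

    @property
    def alpha1(self) -> float:
        """Slow eigen-rate (smaller root)."""
        return self._alphas[0]

    @property
    def alpha2(self) -> float:
        """Fast eigen-rate (larger root)."""
        return self._alphas[1]

    @property
    def bp_nd(self) -> float:
        if self.k4 == 0:
            return 0.0 if self.k3 == 0 else math.inf
        return self.k3 / self.k4

    @property
    def dvr(self) -> float:
        return 1.0 + self.bp_nd

    @property
    def vt(self) -> float:
        """Total distribution volume (K1/k2)(1 + k3/k4)."""
        if self.k2 == 0:
            return math.inf
        return (self.K1 / self.k2) * self.dvr

    @property
    def k2a(self) -> float:
        """Effective washout rate of the late 1-tissue approximation."""
        return self.k2 / self.dvr


@dataclass(frozen=True)
class LoganResult:
    """Slope/intercept of a graphical-analysis fit over a time window."""

    slope: float
    intercept: float
    fit_window: tuple[float, float]
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a graphical fit needs at least 2 points")


# ---------------------------------------------------------------------------
# numerical kernels
# ---------------------------------------------------------------------------


def _nodes(tac: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Integration nodes: frame midpoints with a (0, 0) node prepended."""
    t = np.concatenate([[0.0], tac.midpoint])
    v = np.concatenate([[0.0], tac.values])
    return t, v


def trapz_integral(tac: TimeActivityCurve, T: float) -> float:
    """Trapezoidal integral of the curve from 0 to T minutes.

    The curve is treated as piecewise linear between a (0, 0) node and the
    frame-midpoint samples.  T must lie within [0, last midpoint]; the final
    partial segment is interpolated linearly.
    """
    t, v = _nodes(tac)
    if T < 0 or T > t[-1] + 1e-9:
        raise ValueError(f"T={T} outside integrable range [0, {t[-1]}]")
    T = min(float(T), float(t[-1]))
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])
    return float(np.interp(T, t, cum))


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Trapezoidal ∫₀ᵀ C dt evaluated at every frame midpoint."""
    t, v = _nodes(tac)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])
    return cum[1:]


def finite_diff_derivative(
    tac: TimeActivityCurve,
    smoothing: float | str | None = None,
    method: str = "central",
) -> TimeActivityCurve:
    """Time derivative of a curve at its frame midpoints.

    ``method='central'``: central differences on the (non-uniform) midpoint
    grid, one-sided at the two ends.  ``method='spline'``: derivative of an
    interpolating cubic spline — markedly more accurate on smooth curves
    sampled on wide late frames.

    For noisy data the values can first be replaced by a cubic smoothing
    spline: ``smoothing='gcv'`` picks the penalty by generalized
    cross-validation (recommended); a float is passed to
    ``UnivariateSpline`` as its residual target ``s``.  Either way the fit
    is weighted by the PET-like noise model (variance ~ activity/duration).
    """
    if tac.schedule.F < 3:
        raise ValueError("derivative needs at least 3 frames")
    t = tac.midpoint
    v = tac.values
    if smoothing is not None:
        var = np.maximum(np.abs(v), 0.05 * np.max(np.abs(v)) + 1e-30) / tac.schedule.duration
        if smoothing == "gcv":
            from scipy.interpolate import make_smoothing_spline

            spl = make_smoothing_spline(t, v, w=1.0 / var)
        else:
            spl = UnivariateSpline(t, v, w=1.0 / np.sqrt(var), k=3, s=float(smoothing))
        if method == "spline":
            dv = spl.derivative()(t)
            return TimeActivityCurve(tac.schedule, dv, role="rate")
        v = spl(t)
    if method == "central":
        dv = np.gradient(v, t)
    elif method == "spline":
        from scipy.interpolate import CubicSpline

        dv = CubicSpline(t, v).derivative()(t)
    else:
        raise ValueError("method must be 'central' or 'spline'")
    return TimeActivityCurve(tac.schedule, dv, role="rate")


def _dense_grid(span: float, dt: float) -> np.ndarray:
    n = int(math.ceil(span / dt)) + 1
    t = np.linspace(0.0, span, n)
    return t


def _aif_on_grid(
    aif: Union[TimeActivityCurve, Callable[[np.ndarray], np.ndarray]],
    t: np.ndarray,
) -> np.ndarray:
    """Input curve on the dense grid.

    Callables are evaluated directly.  Sampled curves are interpolated with
    a monotone cubic (PCHIP) through the (0, 0) + midpoint nodes: linear
    interpolation systematically overestimates the convex decaying tail on
    wide late frames, which biases everything downstream of ∫C_P.
    """
    if callable(aif):
        return np.asarray(aif(t), dtype=float)
    from scipy.interpolate import PchipInterpolator

    tn, vn = _nodes(aif)
    vals = PchipInterpolator(tn, vn, extrapolate=False)(t)
    # hold the last sample beyond the final midpoint
    return np.where(np.isnan(vals), vn[-1], vals)


def _exp_conv(alpha: float, t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Convolution e^{-alpha t} ⊗ x on a uniform grid, exact for piecewise-linear x."""
    dt = t[1] - t[0]
    e = math.exp(-alpha * dt)
    if alpha > 0:
        i0 = (1.0 - e) / alpha
        i1 = (1.0 - (1.0 + alpha * dt) * e) / (alpha * alpha)
    else:
        i0 = dt
        i1 = 0.5 * dt * dt
    b0 = i0 - i1 / dt
    b1 = i1 / dt
    y = lfilter([b0, b1], [1.0, -e], x)
    # enforce y(0) = 0: remove the homogeneous response seeded by lfilter's y[0]
    y -= (b0 * x[0]) * np.exp(-alpha * t)
    return y


def _frame_average(t: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a dense curve over each frame's [start, end] interval."""
    dt = t[1] - t[0]
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * dt)])
    lo = np.interp(schedule.start, t, cum)
    hi = np.interp(np.minimum(schedule.end, t[-1]), t, cum)
    width = np.minimum(schedule.end, t[-1]) - schedule.start
    return (hi - lo) / width


def forward_2tc(
    params: Kinetics2TC,
    aif: Union[TimeActivityCurve, Callable[[np.ndarray], np.ndarray]],
    schedule: FrameSchedule | None = None,
    dt_internal: float = 0.05,
) -> TimeActivityCurve:
    """Tissue curve predicted by the two-tissue compartment model.

    Evaluates the bi-exponential impulse response convolved with the plasma
    input on a dense uniform grid (step ``dt_internal`` minutes), then
    averages over each frame interval.  With k3 = k4 = 0 this reduces
    continuously to the one-tissue solution K1·e^{−k2 t} ⊗ C_P.

    ``aif`` may be a plasma-role curve (linearly interpolated through a
    (0, 0) node) or a callable evaluating the input on a time array.
    """
    if isinstance(aif, TimeActivityCurve):
        if aif.role not in ("plasma", "whole_blood"):
            raise ValueError("forward model input curve must have a blood role")
        if schedule is None:
            schedule = aif.schedule
    if schedule is None:
        raise ValueError("schedule required when aif is a callable")

    K1, k2, k3, k4 = params.K1, params.k2, params.k3, params.k4
    t = _dense_grid(schedule.span, dt_internal)
    if K1 == 0.0:
        return TimeActivityCurve(schedule, np.zeros(schedule.F), role="tissue")
    cp = _aif_on_grid(aif, t)

    a1, a2 = params.alpha1, params.alpha2
    if a2 - a1 > 1e-9 * max(a2, 1.0):
        c1 = K1 * (k3 + k4 - a1) / (a2 - a1)
        c2 = K1 * (a2 - k3 - k4) / (a2 - a1)
        y = c1 * _exp_conv(a1, t, cp) + c2 * _exp_conv(a2, t, cp)
    else:
        # degenerate repeated root: h(t) = K1 e^{-a t} (1 + (k3 + k4 - a) t)
        a = 0.5 * (a1 + a2)
        h = K1 * np.exp(-a * t) * (1.0 + (k3 + k4 - a) * t)
        dt = t[1] - t[0]
        full = np.convolve(h, cp)[: t.size] * dt
        y = full - 0.5 * dt * (h[0] * cp + h * cp[0])

    return TimeActivityCurve(schedule, _frame_average(t, y, schedule), role="tissue")


def forward_1tc(
    K1: float,
    k2: float,
    aif: Union[TimeActivityCurve, Callable[[np.ndarray], np.ndarray]],
    schedule: FrameSchedule | None = None,
    dt_internal: float = 0.05,
) -> TimeActivityCurve:
    """One-tissue forward solution; identical to :func:`forward_2tc` with k3 = k4 = 0."""
    return forward_2tc(Kinetics2TC(K1, k2, 0.0, 0.0), aif, schedule, dt_internal)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_TIME_COLS = ("frame_start_min", "frame_duration_min")


def read_tacs_csv(path) -> dict[str, TimeActivityCurve]:
    """Read regional curves from the package CSV dialect.

    Columns: ``frame_start_min``, ``frame_duration_min``, then one column per
    region.  Region columns named ``plasma``/``whole_blood``/``arterial_roi``/
    ``background`` get the matching role; everything else is ``tissue``.
    """
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    for col in _TIME_COLS:
        if col not in df.columns:
            raise ValueError(f"TAC CSV missing required column {col!r}")
    schedule = FrameSchedule(
        df["frame_start_min"].to_numpy(float), df["frame_duration_min"].to_numpy(float)
    )
    out: dict[str, TimeActivityCurve] = {}
    for col in df.columns:
        if col in _TIME_COLS:
            continue
        role = col if col in ROLES and col != "tissue" else "tissue"
        out[col] = TimeActivityCurve(schedule, df[col].to_numpy(float), role=role)
    return out


def write_tacs_csv(path, tacs: dict[str, TimeActivityCurve]) -> None:
    """Write regional curves in the package CSV dialect (shared schedule)."""
    import pandas as pd

    if not tacs:
        raise ValueError("no curves to write")
    schedules = list({id(t.schedule): t.schedule for t in tacs.values()}.values())
    first = schedules[0]
    if any(s != first for s in schedules[1:]):
        raise ValueError("all curves must share one schedule")
    data = {
        "frame_start_min": first.start,
        "frame_duration_min": first.duration,
    }
    data.update({name: tac.values for name, tac in tacs.items()})
    pd.DataFrame(data).to_csv(path, index=False)
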