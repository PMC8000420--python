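"""Post-revision drainage flow: power-law trendline and stepwise pump schedule.

Clinical studies of drainage after knee arthroplasty revision show a flow rate
that decays roughly as a power law of time post-op.  The reactor is driven by a
piecewise-constant approximation of that curve because a peristaltic pump
cannot follow a continuous function.  Times are in hours throughout; flow rates
in mL/min (the mixed unit convention used clinically).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLINICAL_SAMPLING_TIMES_H",
    "DEFAULT_INITIAL_CAP_ML_MIN",
    "DrainageTrendline",
    "ClinicalDrainagePoint",
    "StepwiseSchedule",
    "evaluate_trendline",
    "fit_power_law",
    "build_stepwise_schedule",
    "default_drainage_schedule",
    "flow_at",
    "cumulative_volume",
    "read_drainage_points_csv",
]

#: Effluent sampling times in hours: every 5 min through 55 min, then hourly
#: through 8 h, then 12, 18, 24 and 48 h.  These double as the pump's step
#: boundaries when discretizing the drainage curve.
CLINICAL_SAMPLING_TIMES_H: tuple[float, ...] = tuple(m / 60.0 for m in range(5, 60, 5)) + (
    1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 12.0, 18.0, 24.0, 48.0,
)

#: Initial flow cap, mL/min, back-extrapolated from the clinical drainage data
#: (the power-law curve diverges at t -> 0 and must be capped).
DEFAULT_INITIAL_CAP_ML_MIN = 3.5


@dataclass(frozen=True)
class DrainageTrendline:
    """Power-law drainage curve ``flow = coefficient * t ** exponent``.

    Parameters
    ----------
    coefficient : float
        Flow rate at unit time (mL/min at ``t = 1`` time unit).  Must be > 0.
    exponent : float
        Dimensionless decay exponent.  Must be < 0 (drainage declines).
    time_unit : str
        Unit of the time axis; hours by default.
    """

    coefficient: float = 3.1269
    exponent: float = -1.019
    time_unit: str = "h"

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError(f"trendline coefficient must be > 0, got {self.coefficient}")
        if not self.exponent < 0:
            raise ValueError(f"trendline exponent must be < 0, got {self.exponent}")

    def __call__(self, t):
        """Evaluate the flow rate (mL/min) at time ``t`` (> 0)."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("trendline diverges at t <= 0; evaluate only for t > 0")
        out = self.coefficient * t ** self.exponent
        return float(out) if out.ndim == 0 else out

    def cap_crossing_time(self, cap: float) -> float:
        """Time at which the curve falls to ``cap`` (before which a cap binds)."""
        return (cap / self.coefficient) ** (1.0 / self.exponent)


@dataclass(frozen=True)
class ClinicalDrainagePoint:
    """One observed drainage measurement: time post-op (h) and flow (mL/min)."""

    time_h: float
    flow_ml_min: float

    def __post_init__(self) -> None:
        if not self.time_h > 0:
            raise ValueError("drainage observation time must be > 0")
        if self.flow_ml_min < 0:
            raise ValueError("drainage flow must be >= 0")


def evaluate_trendline(trendline: DrainageTrendline, t):
    """Evaluate ``trendline`` at time(s) ``t`` in hours; returns mL/min."""
    return trendline(t)


def fit_power_law(points, flows=None) -> DrainageTrendline:
    """Fit a power-law trendline to drainage observations by log-log OLS.

    Ordinary least squares on ``log(flow) ~ log(time)``: standard for power-law
    trendlines and matched to multiplicative measurement error.

    Parameters
    ----------
    points
        Either a sequence of :class:`ClinicalDrainagePoint`, a DataFrame with
        columns ``time_h`` and ``flow_ml_min``, or an array of times (h) with
        ``flows`` given separately.
    flows
        Flow rates (mL/min) if ``points`` is an array of times.
    """
    if flows is not None:
        times = np.asarray(points, dtype=float)
        flows = np.asarray(flows, dtype=float)
    elif isinstance(points, pd.DataFrame):
        times = points["time_h"].to_numpy(dtype=float)
        flows = points["flow_ml_min"].to_numpy(dtype=float)
    else:
        pts = list(points)
        times = np.array([p.time_h for p in pts], dtype=float)
        flows = np.array([p.flow_ml_min for p in pts], dtype=float)

    if np.any(times <= 0):
        raise ValueError("all observation times must be > 0")
    if np.any(flows <= 0):
        raise ValueError("power-law fitting requires strictly positive flows")
    if np.unique(times).size < 2:
        raise ValueError("need at least 2 observations with distinct times")

    slope, intercept = np.polyfit(np.log(times), np.log(flows), 1)
    return DrainageTrendline(coefficient=float(np.exp(intercept)), exponent=float(slope))


@dataclass(frozen=True)
class StepwiseSchedule:
    """Piecewise-constant pump flow over ``[0, duration]``.

    Steps are half-open ``[start, end)`` so lookup at a boundary is
    unambiguous; the final step is closed at ``duration``.  Flows must be
    non-increasing (drainage only declines) and the first step equals the
    initial cap.
    """

    starts: tuple[float, ...]
    ends: tuple[float, ...]
    flows_ml_min: tuple[float, ...]
    initial_cap_ml_min: float

    def __post_init__(self) -> None:
        s, e, f = map(np.asarray, (self.starts, self.ends, self.flows_ml_min))
        if not (len(s) == len(e) == len(f)) or len(s) == 0:
            raise ValueError("schedule needs equal-length, non-empty step arrays")
        if s[0] != 0.0:
            raise ValueError("schedule must start at t = 0")
        if np.any(e <= s):
            raise ValueError("each step must have end > start")
        if len(s) > 1 and not np.allclose(s[1:], e[:-1]):
            raise ValueError("steps must be contiguous and non-overlapping")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("step flows must be non-increasing")
        if not np.isclose(f[0], self.initial_cap_ml_min):
            raise ValueError("first step flow must equal the initial cap")

    @property
    def duration_h(self) -> float:
        return self.ends[-1]

    def flow_at(self, t) -> float | np.ndarray:
        """Flow (mL/min) at time ``t`` in hours; ``t = duration`` uses the last step."""
        t_arr = np.asarray(t, dtype=float)
        if np.any((t_arr < 0) | (t_arr > self.duration_h)):
            raise ValueError(f"t must lie in [0, {self.duration_h}] h")
        idx = np.searchsorted(np.asarray(self.starts), t_arr, side="right") - 1
        out = np.asarray(self.flows_ml_min)[idx]
        return float(out) if np.ndim(t) == 0 else out

    def cumulative_volume(self, t: float) -> float:
        """Total volume pumped (mL) through time ``t`` (hours)."""
        if not 0 <= t <= self.duration_h + 1e-12:
            raise ValueError(f"t must lie in [0, {self.duration_h}] h")
        s = np.asarray(self.starts)
        e = np.asarray(self.ends)
        f = np.asarray(self.flows_ml_min)
        overlap_h = np.clip(np.minimum(e, t) - s, 0.0, None)
        return float(np.sum(f * overlap_h * 60.0))  # mL/min * min

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_h": self.starts, "end_h": self.ends, "flow_ml_min": self.flows_ml_min}
        )


def build_stepwise_schedule(
    trendline: DrainageTrendline,
    boundaries: Sequence[float] | None = None,
    initial_cap_ml_min: float = DEFAULT_INITIAL_CAP_ML_MIN,
    duration_h: float = 48.0,
) -> StepwiseSchedule:
    """Discretize the drainage trendline into pump-programmable steps.

    Each step takes ``min(cap, trendline(step start))``; the step starting at
    t = 0, where the power law diverges, takes the cap.  With the default
    boundaries (the effluent sampling times) the cap binds until the trendline
    crosses it at ~0.895 h.

    An empty/None boundary list yields a single constant step at the cap.
    """
    if initial_cap_ml_min <= 0:
        raise ValueError("initial cap must be > 0")
    if duration_h <= 0:
        raise ValueError("duration must be > 0")
    if boundaries is None:
        boundaries = [t for t in CLINICAL_SAMPLING_TIMES_H if t < duration_h]
    b = np.asarray(sorted(boundaries), dtype=float)
    b = b[(b > 0) & (b < duration_h)]
    if b.size and np.any(np.diff(b) <= 0):
        raise ValueError("step boundaries must be strictly increasing")

    starts = np.concatenate([[0.0], b])
    ends = np.concatenate([b, [duration_h]])
    flows = np.empty_like(starts)
    flows[0] = initial_cap_ml_min
    if starts.size > 1:
        flows[1:] = np.minimum(initial_cap_ml_min, trendline(starts[1:]))
    return StepwiseSchedule(
        starts=tuple(starts),
        ends=tuple(ends),
        flows_ml_min=tuple(flows),
        initial_cap_ml_min=initial_cap_ml_min,
    )


def default_drainage_schedule(duration_h: float = 48.0) -> StepwiseSchedule:
    """The reference schedule: clinical trendline, 3.5 mL/min cap, sampling-time steps."""
    return build_stepwise_schedule(DrainageTrendline(), duration_h=duration_h)


def flow_at(schedule: StepwiseSchedule, t):
    """Flow (mL/min) of the step containing ``t`` (hours)."""
    return schedule.flow_at(t)


def cumulative_volume(schedule: StepwiseSchedule, t: float) -> float:
    """Volume pumped (mL) over ``[0, t]`` hours."""
    return schedule.cumulative_volume(t)


def read_drainage_points_csv(path) -> pd.DataFrame:
    """Read clinical drainage observations (columns ``time_h``, ``flow_ml_min``)."""
    df = pd.read_csv(path)
    missing = {"time_h", "flow_ml_min"} - set(df.columns)
    if missing:
        raise ValueError(f"drainage CSV missing required columns: {sorted(missing)}")
    return df
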