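"""Time-dependent parameter schedules for pump and bias.

A schedule is a callable ``t -> value`` where the value is either a scalar
(broadcast over all neurons) or an array of per-neuron values.  Schedules
must be defined on the whole integration window ``[0, duration]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Schedule", "constant", "linear_ramp", "tabulated"]


class Schedule:
    """Base class; subclasses implement ``__call__(t)``."""

    def __call__(self, t: float):  # pragma: no cover - abstract
        raise NotImplementedError

    def describe(self) -> dict:
        return {"kind": type(self).__name__}


@dataclass
class ConstantSchedule(Schedule):
    value: np.ndarray | float

    def __call__(self, t: float):
        return self.value

    def describe(self) -> dict:
        return {"kind": "constant", "value": np.asarray(self.value).tolist()}


@dataclass
class LinearRamp(Schedule):
    """Linear interpolation from ``start`` at t0 to ``stop`` at t1.

    Values are held at the endpoints outside [t0, t1], so the schedule is
    defined for every t >= 0.
    """

    start: np.ndarray | float
    stop: np.ndarray | float
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if not self.t1 > self.t0:
            raise ValueError("linear ramp requires t1 > t0")
        # a degenerate ramp is exactly a constant schedule
        self._constant = np.array_equal(
            np.asarray(self.start), np.asarray(self.stop)
        )

    def __call__(self, t: float):
        if self._constant:
            return np.asarray(self.start)
        s = np.clip((t - self.t0) / (self.t1 - self.t0), 0.0, 1.0)
        return (1.0 - s) * np.asarray(self.start) + s * np.asarray(self.stop)

    def describe(self) -> dict:
        return {
            "kind": "linear_ramp",
            "start": np.asarray(self.start).tolist(),
            "stop": np.asarray(self.stop).tolist(),
            "t0": self.t0,
            "t1": self.t1,
        }


@dataclass
class TabulatedSchedule(Schedule):
    """Piecewise-linear interpolation through tabulated (time, value) pairs."""

    times: np.ndarray
    values: np.ndarray  # shape (T,) or (T, n)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("tabulated schedule needs >= 2 time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("tabulated schedule times must be increasing")
        if self.values.shape[0] != self.times.shape[0]:
            raise ValueError("values must have one row per time point")

    def __call__(self, t: float):
        if self.values.ndim == 1:
            return np.interp(t, self.times, self.values)
        return np.array(
            [np.interp(t, self.times, col) for col in self.values.T]
        )

    def coverage(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def describe(self) -> dict:
        return {"kind": "tabulated", "n_points": len(self.times)}


def constant(value) -> ConstantSchedule:
    return ConstantSchedule(value)


def linear_ramp(start, stop, t0: float, t1: float) -> LinearRamp:
    return LinearRamp(start, stop, t0, t1)


def tabulated(times, values) -> TabulatedSchedule:
    return TabulatedSchedule(np.asarray(times), np.asarray(values))
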