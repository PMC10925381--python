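"""Nonnegative time-varying rate functions on [0, t_max].

Time ``tau`` is measured *before the present*: ``tau = 0`` is the present day
and ``tau = t_max`` is the origin of the process.  Three realizations are
provided:

* :class:`ConstantRate` -- a single nonnegative value;
* :class:`PiecewiseConstantRate` -- right-continuous in ``tau`` with jumps at
  the given breakpoints (the smaller-``tau`` value applies strictly below a
  breakpoint, i.e. from the breakpoint toward the present);
* :class:`GridRate` -- linear interpolation of values on a time grid.

Every rate supports ``value_at`` (scalar or vectorized) and
``upper_bound_on(lo, hi)``, a finite bound on the supremum over ``[lo, hi]``
needed for Poisson thinning.
"""

from __future__ import annotations

import bisect
from typing import Sequence

import numpy as np

__all__ = [
    "RateFunction",
    "ConstantRate",
    "PiecewiseConstantRate",
    "GridRate",
    "as_rate",
]


class RateFunction:
    """Abstract nonnegative function of time-before-present."""

    #: True when the function is exactly piecewise constant, enabling exact
    #: waiting-time inversion in the simulator.
    is_piecewise_constant: bool = False

    def value_at(self, tau):
        raise NotImplementedError

    def upper_bound_on(self, lo: float, hi: float) -> float:
        """Finite bound >= sup of ``value_at`` over ``[lo, hi]``."""
        raise NotImplementedError

    def jump_points(self, lo: float, hi: float) -> list[float]:
        """Discontinuity locations strictly inside ``(lo, hi)``."""
        return []

    def is_zero(self) -> bool:
        """True if the function is identically zero (used for validation
        shortcuts; conservative False is always allowed)."""
        return False

    def fingerprint(self) -> tuple:
        raise NotImplementedError

    def __call__(self, tau):
        return self.value_at(tau)


class ConstantRate(RateFunction):
    is_piecewise_constant = True

    def __init__(self, value: float):
        value = float(value)
        if not np.isfinite(value):
            raise ValueError("rate value must be finite")
        self.value = value

    def value_at(self, tau):
        if np.ndim(tau) == 0:
            return self.value
        return np.full(np.shape(tau), self.value)

    def upper_bound_on(self, lo, hi):
        return self.value

    def is_zero(self):
        return self.value == 0.0

    def fingerprint(self):
        return ("const", self.value)

    def __repr__(self):
        return f"ConstantRate({self.value!r})"


class PiecewiseConstantRate(RateFunction):
    """Right-continuous step function of ``tau``.

    ``values[i]`` applies on ``[breakpoints[i-1], breakpoints[i])`` with the
    conventions ``breakpoints[-1] = -inf`` and ``breakpoints[len] = +inf``;
    i.e. ``values[0]`` holds on ``[0, breakpoints[0])`` (nearest the present)
    and ``values[-1]`` from the last breakpoint back to the origin.
    """

    is_piecewise_constant = True

    def __init__(self, breakpoints: Sequence[float], values: Sequence[float]):
        bp = [float(b) for b in breakpoints]
        vals = [float(v) for v in values]
        if len(vals) != len(bp) + 1:
            raise ValueError(
                "need len(values) == len(breakpoints) + 1 "
                f"(got {len(vals)} values, {len(bp)} breakpoints)"
            )
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if bp and bp[0] <= 0:
            raise ValueError("breakpoints must be > 0 (tau before present)")
        self.breakpoints = bp
        self.values = vals
        self._bp_arr = np.asarray(bp)
        self._val_arr = np.asarray(vals)

    def value_at(self, tau):
        if np.ndim(tau) == 0:
            return self.values[bisect.bisect_right(self.breakpoints, tau)]
        idx = np.searchsorted(self._bp_arr, np.asarray(tau), side="right")
        return self._val_arr[idx]

    def upper_bound_on(self, lo, hi):
        i = bisect.bisect_right(self.breakpoints, lo)
        j = bisect.bisect_right(self.breakpoints, hi)
        return max(self.values[i : j + 1])

    def jump_points(self, lo, hi):
        i = bisect.bisect_right(self.breakpoints, lo)
        j = bisect.bisect_left(self.breakpoints, hi)
        return self.breakpoints[i:j]

    def is_zero(self):
        return all(v == 0.0 for v in self.values)

    def fingerprint(self):
        return ("pw", tuple(self.breakpoints), tuple(self.values))

    def __repr__(self):
        return f"PiecewiseConstantRate({self.breakpoints!r}, {self.values!r})"


class GridRate(RateFunction):
    """Linear interpolant of ``values`` at grid ``times`` (constant beyond
    the grid ends).  The supremum over a window is attained at a knot or a
    window endpoint, so ``upper_bound_on`` is exact."""

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("grid and values must be 1-d arrays of equal length >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("grid times must be strictly increasing")
        self.times = t
        self.values = v

    def value_at(self, tau):
        return np.interp(tau, self.times, self.values)

    def upper_bound_on(self, lo, hi):
        inside = self.values[(self.times >= lo) & (self.times <= hi)]
        cands = [float(self.value_at(lo)), float(self.value_at(hi))]
        if inside.size:
            cands.append(float(inside.max()))
        return max(cands)

    def is_zero(self):
        return bool(np.all(self.values == 0.0))

    def fingerprint(self):
        return ("grid", self.times.tobytes(), self.values.tobytes())

    def __repr__(self):
        return f"GridRate(<{self.times.size} knots on [{self.times[0]}, {self.times[-1]}]>)"


def as_rate(spec, *, name: str = "rate") -> RateFunction:
    """Coerce a config cell into a :class:`RateFunction`.

    Accepts a number (constant), a ``RateFunction``, or a mapping with keys
    ``breakpoints``/``values`` (piecewise constant) or ``times``/``values``
    (grid interpolant).
    """
    if isinstance(spec, RateFunction):
        return spec
    if isinstance(spec, (int, float)):
        return ConstantRate(spec)
    if isinstance(spec, dict):
        keys = set(spec)
        if keys == {"breakpoints", "values"}:
            return PiecewiseConstantRate(spec["breakpoints"], spec["values"])
        if keys == {"times", "values"}:
            return GridRate(spec["times"], spec["values"])
        raise ValueError(
            f"{name}: mapping must have keys {{breakpoints, values}} or "
            f"{{times, values}}, got {sorted(keys)}"
        )
    raise TypeError(f"{name}: cannot interpret {spec!r} as a rate function")
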