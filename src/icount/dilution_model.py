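"""Closed-form mathematics of fluorescent tag dilution across cell divisions.

A recombination event switches new synthesis of a stable, cell-cycle-
replenished protein (e.g. a replication-coupled histone) from an "old"
red tag to a "new" green tag.  Every completed division then halves the
old-tag content of a cell while the pool is refilled with new-tag
protein.  With ``C`` the baseline brightness ratio of the old reporter
to the new one, the green-to-total fluorescence fraction after ``n``
completed divisions is

    R(n) = (2**n - 1) / (C + 2**n - 1)

which at ``C == 1`` inverts to ``n = -log2(1 - R)`` and yields the class
boundaries 50%, 75%, 87.5% and 93.75% for 1, 2, 3 and 4 divisions.

This module provides the forward model, its inverse, the division-class
binning, deterministic theoretical trajectories for two- and three-color
reporters, and the three-color (dual-switch) closed form.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DIVISION_CLASSES",
    "CLASS_LOWER_BOUNDS",
    "POOL_LEVEL",
    "UnboundedEstimateError",
    "DivisionEstimate",
    "green_fraction_after_divisions",
    "estimate_divisions",
    "classify_division_number",
    "micount_fractions",
    "TheoreticalTrajectory",
    "theoretical_trajectory",
    "interval_mean_trajectory",
    "ChannelMeans",
]

#: Division classes, in order of increasing green fraction.
DIVISION_CLASSES = ("0-1", "1-2", "2-3", "3-4", "4+")

#: Lower (inclusive) green-fraction bound of each division class.  Each
#: class covers ``[lower, next_lower)``; the last class covers
#: ``[0.9375, 1]``.
CLASS_LOWER_BOUNDS = (0.0, 0.5, 0.75, 0.875, 0.9375)

#: Normalized level of the complete protein pool in theoretical
#: trajectories (old-tag level before the first division).
POOL_LEVEL = 100.0

_LN2 = math.log(2.0)


class UnboundedEstimateError(ValueError):
    """Raised when a green fraction of exactly 1 makes the continuous
    division estimate unbounded (any sufficiently large division number
    is indistinguishable)."""


def _validate_count(n, name: str = "n") -> int:
    if isinstance(n, bool) or not isinstance(n, (int, np.integer)):
        if isinstance(n, float) and n.is_integer():
            n = int(n)
        else:
            raise TypeError(f"{name} must be a nonnegative integer, got {n!r}")
    if n < 0:
        raise ValueError(f"{name} must be nonnegative, got {n}")
    return int(n)


def _validate_baseline_ratio(c) -> float:
    c = float(c)
    if not c > 0 or not math.isfinite(c):
        raise ValueError(f"baseline ratio C must be positive and finite, got {c}")
    return c


def green_fraction_after_divisions(n: int, c: float = 1.0) -> float:
    """Green-to-total fluorescence fraction after ``n`` completed divisions.

    Parameters
    ----------
    n : int
        Number of completed divisions since the tag switch.  Must be a
        nonnegative integer.
    c : float, optional
        Baseline old-to-new reporter brightness ratio.  ``c == 1`` means
        equally bright reporters (the default used throughout).

    Returns
    -------
    float
        ``R = (2**n - 1) / (c + 2**n - 1)``, in ``[0, 1)``.  ``R == 0``
        at ``n == 0`` and ``R`` increases strictly toward 1 with ``n``.
    """
    n = _validate_count(n)
    c = _validate_baseline_ratio(c)
    x = math.pow(2.0, n) - 1.0
    return x / (c + x)


def estimate_divisions(r: float, c: float = 1.0) -> float:
    """Continuous division-number estimate from a green fraction.

    Exact inverse of :func:`green_fraction_after_divisions`:
    ``n_hat = log2(1 + c * r / (1 - r))``, computed through ``log1p`` for
    accuracy close to ``r == 1``.  At ``c == 1`` this reduces to
    ``-ln(1 - r) / ln 2``.

    Raises
    ------
    UnboundedEstimateError
        If ``r == 1`` (estimate unbounded).
    ValueError
        If ``r`` lies outside ``[0, 1]``.
    """
    r = float(r)
    c = _validate_baseline_ratio(c)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"green fraction must lie in [0, 1], got {r}")
    if r == 1.0:
        raise UnboundedEstimateError(
            "green fraction of 1 gives an unbounded division estimate"
        )
    # n = log2((1 - r + c*r) / (1 - r)) split into two log1p terms.
    return (math.log1p(r * (c - 1.0)) - math.log1p(-r)) / _LN2


def classify_division_number(r: float) -> str:
    """Bin a green fraction into one of the five division classes.

    Classes use half-open intervals ``[lower, upper)`` with boundaries
    at 0.5, 0.75, 0.875 and 0.9375; the top class ``"4+"`` covers
    ``[0.9375, 1]``.  Equivalent to ``min(floor(estimate_divisions(r, 1)), 4)``.
    """
    r = float(r)
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"green fraction must lie in [0, 1], got {r}")
    return DIVISION_CLASSES[bisect_right(CLASS_LOWER_BOUNDS, r) - 1]


@dataclass(frozen=True)
class DivisionEstimate:
    """Continuous division estimate plus its binned class.

    ``n_hat`` is ``math.inf`` when the green fraction equals 1, in which
    case the class is ``"4+"``.
    """

    n_hat: float
    div_class: str

    def __post_init__(self) -> None:
        if self.n_hat < 0:
            raise ValueError("n_hat must be nonnegative")
        if self.div_class not in DIVISION_CLASSES:
            raise ValueError(f"unknown division class {self.div_class!r}")

    @classmethod
    def from_green_fraction(cls, r: float, c: float = 1.0) -> "DivisionEstimate":
        try:
            n_hat = estimate_divisions(r, c)
        except UnboundedEstimateError:
            n_hat = math.inf
        return cls(n_hat=n_hat, div_class=classify_division_number(r))


def micount_fractions(n_pre: int, n_post: int) -> tuple[float, float, float]:
    """Three-color pool fractions for the dual-switch reporter.

    ``n_pre`` divisions are completed between the first (red-to-green)
    and the second (green-to-blue) switch, ``n_post`` after the second
    switch.  Assumes equally bright reporters.

    Returns ``(red, green, blue)`` with
    ``red = 2**-(n_pre + n_post)``,
    ``green = (1 - 2**-n_pre) * 2**-n_post`` and
    ``blue = 1 - 2**-n_post``; the fractions sum to 1.
    """
    n_pre = _validate_count(n_pre, "n_pre")
    n_post = _validate_count(n_post, "n_post")
    red = math.pow(2.0, -(n_pre + n_post))
    green = (1.0 - math.pow(2.0, -n_pre)) * math.pow(2.0, -n_post)
    blue = 1.0 - math.pow(2.0, -n_post)
    return (red, green, blue)


class ChannelMeans(NamedTuple):
    red: float
    green: float
    blue: float


class _Segment(NamedTuple):
    """Linear channel course over ``[t0, t1]``."""

    t0: float
    t1: float
    state0: tuple[float, float, float]
    state1: tuple[float, float, float]


@dataclass(frozen=True)
class _Interval:
    index: int
    start: float
    end: float
    segments: tuple[_Segment, ...]

    @property
    def start_state(self) -> tuple[float, float, float]:
        return self.segments[0].state0

    @property
    def end_state(self) -> tuple[float, float, float]:
        return self.segments[-1].state1


@dataclass(frozen=True)
class TheoreticalTrajectory:
    """Deterministic noise-free reporter trajectory.

    The old-tag (red) level is ``POOL_LEVEL`` before the first division
    and halves instantaneously at every division.  Within each
    inter-division interval the newly synthesized channel rises linearly
    from its post-division level so that the channel sum is restored to
    ``POOL_LEVEL`` exactly at the next division instant.  Sampled values
    at division instants are the post-division (right-continuous) ones.
    """

    times: np.ndarray
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    division_times: tuple[float, ...]
    has_blue: bool
    _intervals: tuple[_Interval, ...] = field(repr=False)

    @property
    def n_intervals(self) -> int:
        return len(self._intervals)

    def interval(self, k: int) -> _Interval:
        if not 0 <= k < len(self._intervals):
            raise IndexError(
                f"interval index {k} out of range 0..{len(self._intervals) - 1}"
            )
        return self._intervals[k]

    def state_before_division(self, k: int) -> ChannelMeans:
        """Channel levels at the completion instant of division ``k``
        (1-based), i.e. just before the halving."""
        if not 1 <= k <= len(self.division_times):
            raise IndexError(f"division index {k} out of range")
        return ChannelMeans(*self._intervals[k - 1].end_state)

    def state_after_division(self, k: int) -> ChannelMeans:
        """Channel levels immediately after division ``k`` (1-based)."""
        if not 1 <= k <= len(self.division_times):
            raise IndexError(f"division index {k} out of range")
        if k < len(self._intervals):
            return ChannelMeans(*self._intervals[k].start_state)
        pre = self._intervals[k - 1].end_state
        return ChannelMeans(*(v / 2.0 for v in pre))

    def value_at(self, t: float) -> ChannelMeans:
        """Right-continuous channel levels at time ``t``."""
        for iv in self._intervals:
            if iv.start <= t < iv.end or (iv is self._intervals[-1] and t == iv.end):
                for seg in iv.segments:
                    if seg.t0 <= t <= seg.t1:
                        if seg.t1 == seg.t0:
                            return ChannelMeans(*seg.state1)
                        w = (t - seg.t0) / (seg.t1 - seg.t0)
                        return ChannelMeans(
                            *(a + w * (b - a) for a, b in zip(seg.state0, seg.state1))
                        )
        raise ValueError(f"time {t} outside trajectory support")

    def to_frame(self):
        """Samples as a pandas DataFrame (time, red, green[, blue])."""
        import pandas as pd

        data = {"time": self.times, "red": self.red, "green": self.green}
        if self.has_blue:
            data["blue"] = self.blue
        return pd.DataFrame(data)


def theoretical_trajectory(
    division_times: Sequence[float],
    recombination_time: float = 0.0,
    flp_time: float | None = None,
    sample_step: float = 0.5,
    detection_delay: float = 0.0,
    pool: float = POOL_LEVEL,
) -> TheoreticalTrajectory:
    """Construct the deterministic reporter trajectory.

    Parameters
    ----------
    division_times : sequence of float
        Strictly increasing division instants (hours).
    recombination_time : float
        Instant of the red-to-green switch; must not exceed the first
        division time.
    flp_time : float, optional
        Instant of the second (green-to-blue) switch.  New synthesis in
        intervals after this time is blue, and green thereafter only
        halves at divisions, like red.
    sample_step : float
        Spacing of the regular sample grid (hours).
    detection_delay : float, optional
        Delay between the switch and detectability of the new green
        protein; postpones the onset of the first green ramp.
    pool : float
        Full pool level (default 100).
    """
    division_times = tuple(float(t) for t in division_times)
    if len(division_times) == 0:
        raise ValueError("at least one division time is required")
    if any(b <= a for a, b in zip(division_times, division_times[1:])):
        raise ValueError("division times must be strictly increasing")
    recombination_time = float(recombination_time)
    if recombination_time > division_times[0]:
        raise ValueError("recombination_time must not exceed the first division time")
    if sample_step <= 0:
        raise ValueError("sample_step must be positive")
    if detection_delay < 0:
        raise ValueError("detection_delay must be nonnegative")
    if flp_time is not None:
        flp_time = float(flp_time)
        if flp_time < recombination_time:
            raise ValueError("flp_time must not precede recombination_time")

    boundaries = (recombination_time,) + division_times
    intervals: list[_Interval] = []
    state = np.array([pool, 0.0, 0.0])  # at recombination: full old-tag pool

    for k in range(len(boundaries) - 1):
        t0, t1 = boundaries[k], boundaries[k + 1]
        deficit = pool - state.sum()
        segments: list[_Segment] = []
        if deficit <= 1e-12:
            segments.append(_Segment(t0, t1, tuple(state), tuple(state)))
            end_state = state.copy()
        else:
            ramp_start = t0
            if k == 1 and detection_delay > 0.0:
                # First interval in which green appears: delayed onset.
                ramp_start = min(t0 + detection_delay, t1)
                segments.append(_Segment(t0, ramp_start, tuple(state), tuple(state)))
            # Split the ramp at the second switch if it falls inside.
            cuts = [ramp_start, t1]
            if flp_time is not None and ramp_start < flp_time < t1:
                cuts = [ramp_start, flp_time, t1]
            rate = deficit / (t1 - ramp_start) if t1 > ramp_start else 0.0
            cur = state.copy()
            for a, b in zip(cuts, cuts[1:]):
                nxt = cur.copy()
                channel = 2 if (flp_time is not None and a >= flp_time) else 1
                nxt[channel] += rate * (b - a)
                segments.append(_Segment(a, b, tuple(cur), tuple(nxt)))
                cur = nxt
            end_state = cur
        intervals.append(_Interval(k, t0, t1, tuple(segments)))
        state = end_state / 2.0  # instantaneous halving at the division

    traj_intervals = tuple(intervals)

    # Regular sample grid, augmented with the exact division instants
    # (values there are the post-division ones; right-continuous).
    grid = np.arange(recombination_time, division_times[-1] + 0.5 * sample_step,
                     sample_step)
    times = np.unique(np.concatenate([grid, np.asarray(boundaries)]))
    times = times[(times >= recombination_time) & (times <= division_times[-1])]

    red = np.empty_like(times)
    green = np.empty_like(times)
    blue = np.empty_like(times)
    dummy = TheoreticalTrajectory(
        times=times, red=red, green=green, blue=blue,
        division_times=division_times, has_blue=flp_time is not None,
        _intervals=traj_intervals,
    )
    last_post = np.array(traj_intervals[-1].end_state) / 2.0
    for i, t in enumerate(times):
        if t == division_times[-1]:
            vals = ChannelMeans(*last_post)
        else:
            vals = dummy.value_at(float(t))
        red[i], green[i], blue[i] = vals
    return dummy


def interval_mean_trajectory(traj: TheoreticalTrajectory, k: int) -> ChannelMeans:
    """Time-weighted mean channel levels over the ``k``-th inter-division
    interval.

    ``k`` counts completed divisions during the interval: interval 0 runs
    from recombination to the first division (old tag constant at the
    full pool level, no new tag yet); interval 1 is the first interval in
    which the new tag appears, ramping linearly from 0 to half the pool
    (mean 25 on the 0-100 scale); interval 2 ramps 25 to 75 (mean 50);
    and so on.
    """
    iv = traj.interval(k)
    duration = iv.end - iv.start
    if duration <= 0:
        return ChannelMeans(*iv.end_state)
    acc = np.zeros(3)
    for seg in iv.segments:
        mid = 0.5 * (np.asarray(seg.state0) + np.asarray(seg.state1))
        acc += mid * (seg.t1 - seg.t0)
    return ChannelMeans(*(acc / duration))
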