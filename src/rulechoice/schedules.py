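"""Reinforcement-schedule primitives.

Implements the building blocks of a concurrent variable-interval (VI) /
extinction (EXT) schedule pair as used in multiple-schedule choice
procedures:

* constant-probability VI interval lists generated by the Fleshler-Hoffman
  progression,
* per-alternative schedule state machines (a VI arms a reinforcer when its
  current interval elapses; EXT never arms),
* a concurrent pair with a changeover delay (COD) that blocks responding
  for a fixed period after every switch between alternatives.

The engine is discrete-time with a 10 ms resolution: every duration used by
the session layer (60 s components, 10 s inter-component intervals, 3 s COD,
400 ms stimulus alternation, 235 ms flash) is an integer number of steps, so
all event times are exactly representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal

import numpy as np

from .errors import InvalidParameterError

#: Engine time resolution in seconds.
TIME_STEP_S = 0.01

#: Tolerance used for "a timer reached zero" comparisons on quantised times.
_EPS = 1e-9

Side = Literal["left", "right"]


def other_side(side: Side) -> Side:
    return "right" if side == "left" else "left"


def quantize(t_s: float) -> float:
    """Snap a time (seconds) onto the 10 ms engine grid, rounding half up."""
    return round(math.floor(t_s / TIME_STEP_S + 0.5) * TIME_STEP_S, 6)


def quantize_up(t_s: float) -> float:
    """Snap a positive duration up onto the grid (never below one step)."""
    n = math.ceil(t_s / TIME_STEP_S - _EPS)
    return round(max(n, 1) * TIME_STEP_S, 6)


# ---------------------------------------------------------------------------
# Fleshler-Hoffman interval lists
# ---------------------------------------------------------------------------


@dataclass
class IntervalList:
    """An ordered list of VI intervals sampled without replacement.

    ``intervals_s`` holds the full generated progression; ``remaining`` the
    subset not yet consumed.  When ``remaining`` is exhausted a draw first
    regenerates a fresh copy of the list, so a free-running schedule keeps
    its constant-probability character indefinitely.
    """

    mean_s: float
    n_intervals: int
    intervals_s: tuple[float, ...]
    remaining: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.remaining:
            self.remaining = list(self.intervals_s)

    def draw(self, rng: np.random.Generator) -> float:
        """Draw one interval uniformly at random without replacement.

        Regenerates a fresh copy of the full list first if all intervals
        have been consumed.
        """
        if not self.remaining:
            self.remaining = list(self.intervals_s)
        idx = int(rng.integers(len(self.remaining)))
        return self.remaining.pop(idx)


def fleshler_hoffman_intervals(mean_s: float, n: int) -> IntervalList:
    """Generate an ``n``-interval constant-probability VI list with mean ``mean_s``.

    Uses the closed-form progression

    ``t_k = T * [1 + ln(n) + (n-k) ln(n-k) - (n-k+1) ln(n-k+1)]``

    for ``k = 1..n`` with the convention ``0 ln 0 = 0``.  The ``t_k`` are the
    conditional means of an exponential distribution within ``n``
    equal-probability slices, so a uniform draw from the list approximates an
    exponential inter-setup time and the schedule's reinforcer-setup hazard
    is approximately constant.  The sum of the list telescopes to exactly
    ``n * T``, so its arithmetic mean is the programmed mean.

    Parameters
    ----------
    mean_s : float
        Programmed VI mean ``T`` in seconds; must be positive.
    n : int
        Number of intervals in the list; must be at least 1.
    """
    if not (mean_s > 0):
        raise InvalidParameterError(f"VI mean must be positive, got {mean_s!r}")
    if n < 1:
        raise InvalidParameterError(f"interval count must be >= 1, got {n!r}")
    T = float(mean_s)
    vals = []
    for k in range(1, n + 1):
        a = n - k
        b = n - k + 1
        term = 1.0 + math.log(n) + (a * math.log(a) if a > 0 else 0.0) - b * math.log(b)
        vals.append(T * term)
    return IntervalList(mean_s=T, n_intervals=n, intervals_s=tuple(vals))


def draw_interval(interval_list: IntervalList, rng: np.random.Generator) -> float:
    """Module-level convenience wrapper around :meth:`IntervalList.draw`."""
    return interval_list.draw(rng)


# ---------------------------------------------------------------------------
# Schedule state machines
# ---------------------------------------------------------------------------


class ScheduleKind(str, Enum):
    VI = "VI"
    EXT = "EXT"


@dataclass
class ScheduleState:
    """State of one response alternative's schedule.

    A VI schedule counts down ``time_to_arm_s`` in real time; when the timer
    reaches zero the schedule *arms* (a reinforcer is set up) and stays armed
    until the reinforcer is collected by a response.  EXT never arms.
    """

    kind: ScheduleKind
    interval_list: IntervalList | None = None
    armed: bool = False
    time_to_arm_s: float = math.inf
    armed_at_s: float = math.nan  # pair-clock time the current setup armed

    @classmethod
    def vi(
        cls,
        mean_s: float,
        rng: np.random.Generator,
        n_intervals: int = 20,
        interval_list: IntervalList | None = None,
    ) -> "ScheduleState":
        """A fresh VI schedule with its first interval already drawn."""
        lst = interval_list or fleshler_hoffman_intervals(mean_s, n_intervals)
        first = quantize_up(lst.draw(rng))
        return cls(kind=ScheduleKind.VI, interval_list=lst, time_to_arm_s=first)

    @classmethod
    def ext(cls) -> "ScheduleState":
        return cls(kind=ScheduleKind.EXT)

    def advance(self, dt: float, now_s: float) -> None:
        """Advance the arming timer by ``dt`` seconds ending at ``now_s``."""
        if self.kind is not ScheduleKind.VI or self.armed:
            return
        remaining = round(self.time_to_arm_s - dt, 6)
        if remaining <= _EPS:
            # armed at the instant the interval elapsed, possibly mid-advance
            self.armed = True
            self.armed_at_s = round(now_s + min(remaining, 0.0), 6)
            self.time_to_arm_s = 0.0
        else:
            self.time_to_arm_s = remaining

    def collect(self, rng: np.random.Generator) -> None:
        """Deliver the set-up reinforcer and draw the next interval."""
        if self.kind is not ScheduleKind.VI or not self.armed:
            raise InvalidParameterError("collect() requires an armed VI schedule")
        self.armed = False
        self.armed_at_s = math.nan
        self.time_to_arm_s = quantize_up(self.interval_list.draw(rng))


class Outcome(str, Enum):
    """Result of registering a response on a concurrent pair."""

    RECORDED = "recorded"
    REINFORCED = "reinforced"
    COD_TRIGGERED = "cod_triggered"
    BLOCKED = "blocked"


@dataclass
class ConcurrentPair:
    """A concurrent two-alternative schedule pair with a changeover delay.

    Semantics, in precedence order, for a response at the current time:

    1. While the COD is running the operanda are withdrawn: the response is
       ``BLOCKED`` and has no effect.
    2. A response to the alternative other than ``last_alternative`` (once
       one exists) is a changeover: it starts the COD and counts toward
       neither schedule (``COD_TRIGGERED``).  The first post-COD response to
       the *pre-changeover* alternative is therefore another changeover.
    3. Otherwise the response is ``RECORDED``; if that side's schedule is
       armed it is additionally ``REINFORCED``, which disarms the schedule
       and draws the next interval.

    The first response after component onset only sets ``last_alternative``
    and can never trigger a COD.  Because responses are blocked throughout
    the COD, no reinforcer can ever be delivered within ``cod_duration_s``
    of a changeover.

    ``reinforce_post_cod_unconditionally`` switches to a literal reading of
    the procedure in which the first post-COD response to the switched-to
    alternative is reinforced regardless of arming; it only ever applies to
    a VI alternative (EXT delivers nothing under either reading).
    """

    left: ScheduleState
    right: ScheduleState
    rng: np.random.Generator
    cod_duration_s: float = 3.0
    last_alternative: Literal["left", "right", "none"] = "none"
    cod_remaining_s: float = 0.0
    reinforce_post_cod_unconditionally: bool = False
    t_s: float = 0.0  # component-relative clock
    last_armed_at_s: float = math.nan  # arming time of the last delivered reinforcer
    _post_cod_pending: bool = field(default=False, repr=False)

    def schedule(self, side: Side) -> ScheduleState:
        return self.left if side == "left" else self.right

    @property
    def cod_active(self) -> bool:
        return self.cod_remaining_s > _EPS

    def advance_time(self, dt: float) -> "ConcurrentPair":
        """Advance the pair's clock by ``dt`` seconds; only timers change."""
        if not dt > 0:
            raise InvalidParameterError(f"dt must be positive, got {dt!r}")
        self.t_s = round(self.t_s + dt, 6)
        self.left.advance(dt, self.t_s)
        self.right.advance(dt, self.t_s)
        if self.cod_remaining_s > 0:
            self.cod_remaining_s = max(0.0, round(self.cod_remaining_s - dt, 6))
        return self

    def advance_to(self, t_s: float) -> "ConcurrentPair":
        if t_s > self.t_s + _EPS:
            self.advance_time(round(t_s - self.t_s, 6))
        return self

    def register_response(self, side: Side, t_s: float | None = None) -> Outcome:
        """Register a response on ``side`` at time ``t_s`` (defaults to now)."""
        if t_s is not None:
            self.advance_to(t_s)
        if self.cod_active:
            return Outcome.BLOCKED
        if self.last_alternative != "none" and side != self.last_alternative:
            self.cod_remaining_s = self.cod_duration_s
            self.last_alternative = side
            self._post_cod_pending = True
            return Outcome.COD_TRIGGERED
        self.last_alternative = side
        sched = self.schedule(side)
        unconditional = (
            self._post_cod_pending
            and self.reinforce_post_cod_unconditionally
            and sched.kind is ScheduleKind.VI
        )
        self._post_cod_pending = False
        if sched.kind is ScheduleKind.VI and sched.armed:
            self.last_armed_at_s = sched.armed_at_s
            sched.collect(self.rng)
            return Outcome.REINFORCED
        if unconditional:
            # literal post-COD reading: deliver without a setup; the running
            # interval keeps counting down untouched
            self.last_armed_at_s = math.nan
            return Outcome.REINFORCED
        return Outcome.RECORDED
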