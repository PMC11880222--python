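"""Exposure scenarios: piecewise forcing plus discrete bolus-dose events.

Four canonical two-week scenarios are provided:

1. constant continuous inhalation (constant air concentration);
2. constant continuous oral (constant infusion rate into the stomach lumen);
3. periodic inhalation -- 6 h/day, 5 days/week;
4. periodic oral -- six bolus doses per day, 7 days/week.

Clock times within a day are not part of the scenario contract; windows
start at 09:00 of each exposure day and boluses fall every 4 h starting at
02:00 so that all six fit within one day.
"""

from __future__ import annotations

import bisect
import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError

HOURS_PER_DAY = 24.0
HOURS_PER_WEEK = 168.0


@dataclass(frozen=True)
class BolusEvent:
    """Instantaneous addition of ``amount`` (mg) to ``state`` at ``time`` (h)."""

    time: float
    state: str
    amount: float


@dataclass(frozen=True)
class ExposureSchedule:
    """Forcing functions and event schedule over ``[0, duration]`` hours.

    ``windows`` is a sorted tuple of ``(start, end, level)`` triples giving a
    piecewise-constant inhaled air concentration (mg/L); evaluation is
    right-continuous and zero outside windows.  ``background_oral_rate`` is a
    constant infusion (mg/h) into the stomach lumen.  ``events`` are discrete
    bolus doses.
    """

    route: str  # "inhalation" | "oral"
    duration: float = 336.0  # h
    windows: tuple[tuple[float, float, float], ...] = ()
    events: tuple[BolusEvent, ...] = ()
    background_oral_rate: float = 0.0  # mg/h
    iv_rate: float = 0.0  # mg/h, constant infusion (no preset scenario uses it)
    dermal_rate: float = 0.0  # mg/h applied to the vehicle

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        prev_end = None
        for start, end, level in self.windows:
            if not (0.0 <= start < end <= self.duration):
                raise ValidationError(
                    f"window ({start}, {end}) outside [0, {self.duration}]"
                )
            if level < 0:
                raise ValidationError("forcing must be nonnegative")
            if prev_end is not None and start < prev_end:
                raise ValidationError("windows must be strictly increasing")
            prev_end = end
        for ev in self.events:
            if not (0.0 <= ev.time <= self.duration):
                raise ValidationError(
                    f"event at t={ev.time} outside [0, {self.duration}]"
                )
        if min(self.background_oral_rate, self.iv_rate, self.dermal_rate) < 0:
            raise ValidationError("background rates must be nonnegative")

    # ------------------------------------------------------------------

    def breakpoints(self) -> list[float]:
        """Sorted unique discontinuity times (window edges and event times)."""
        pts = {0.0, self.duration}
        for start, end, _ in self.windows:
            pts.add(start)
            pts.add(end)
        for ev in self.events:
            pts.add(ev.time)
        return sorted(pts)

    def events_at(self, t: float, tol: float = 1e-9) -> list[BolusEvent]:
        return [ev for ev in self.events if abs(ev.time - t) <= tol]

    def total_bolus_mass(self) -> float:
        return sum(ev.amount for ev in self.events)

    def scheduled_oral_intake(self, t: float) -> float:
        """Cumulative oral mass delivered to the stomach lumen by time ``t``.

        Deterministic in the schedule: boluses at times <= t plus the
        background infusion integrated over [0, t].
        """
        bolus = sum(
            ev.amount
            for ev in self.events
            if ev.state == "a_stomach_lumen" and ev.time <= t + 1e-12
        )
        return bolus + self.background_oral_rate * min(t, self.duration)


def forcing_at(schedule: ExposureSchedule, t: float) -> float:
    """Inhaled air concentration (mg/L) at time ``t`` (right-continuous)."""
    if t < 0:
        raise ValidationError("t must be >= 0")
    for start, end, level in schedule.windows:
        if start <= t < end:
            return level
    return 0.0


def make_scenario(
    kind: int, dose_level: float, duration_weeks: float = 2.0
) -> ExposureSchedule:
    """Construct one of the four canonical exposure scenarios.

    Parameters
    ----------
    kind:
        1 constant inhalation, 2 constant oral infusion, 3 periodic
        inhalation (6 h/day, days 1-5 and 8-12), 4 periodic oral boluses
        (6/day, every day).
    dose_level:
        Air concentration in mg/L (kinds 1 and 3), infusion rate in mg/h
        (kind 2), or bolus mass in mg (kind 4).
    """
    if dose_level < 0:
        raise ValidationError("dose_level must be >= 0")
    duration = duration_weeks * HOURS_PER_WEEK
    n_days = int(round(duration / HOURS_PER_DAY))
    if kind == 1:
        return ExposureSchedule(
            route="inhalation",
            duration=duration,
            windows=((0.0, duration, dose_level),),
        )
    if kind == 2:
        return ExposureSchedule(
            route="oral",
            duration=duration,
            background_oral_rate=dose_level,
        )
    if kind == 3:
        windows = []
        for day in range(n_days):
            if day % 7 >= 5:  # weekend
                continue
            start = day * HOURS_PER_DAY + 9.0
            windows.append((start, start + 6.0, dose_level))
        return ExposureSchedule(
            route="inhalation", duration=duration, windows=tuple(windows)
        )
    if kind == 4:
        events = tuple(
            BolusEvent(day * HOURS_PER_DAY + 2.0 + 4.0 * k, "a_stomach_lumen", dose_level)
            for day in range(n_days)
            for k in range(6)
        )
        return ExposureSchedule(route="oral", duration=duration, events=events)
    raise ValidationError(f"unknown scenario kind: {kind!r}")


def write_events_csv(schedule: ExposureSchedule, path: str | Path) -> None:
    """Export the bolus-event list as CSV (time, target_state, increment)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "target_state", "increment"])
        for ev in schedule.events:
            writer.writerow([ev.time, ev.state, ev.amount])
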