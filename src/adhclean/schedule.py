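"""Expected-opening schedules: continuous and cyclic (On/Off) regimens.

For every monitor-day inside a monitoring window the prescribed regimen
implies an expected number of EM openings. A continuous regimen expects
the same count every day. A cyclic regimen (e.g. palbociclib 21 days on /
7 days off) expects ``expected_openings`` during the first ``on_days`` of
each cycle and 0 during the following ``off_days``; the cycle phase is
anchored at the regimen period's start date. Regimen changes are
expressed as consecutive periods; each period restarts its own cycle.

Schedules are truncated to the monitoring window (both interval ends
inclusive throughout — an off-by-one here would change every
implementation denominator).
"""

from __future__ import annotations

import datetime as dt

from .aux_schema import MonitorWindow, RegimenPeriod
from .dates import date_range


class ScheduleError(ValueError):
    """Raised on regimen defects that upstream validation should have caught."""


def expected_on(period: RegimenPeriod, date: dt.date) -> int:
    """Expected openings implied by ``period`` on ``date`` (must be covered)."""
    if not period.start_date <= date <= period.end_date:
        raise ScheduleError(f"{date} outside regimen period")
    if not period.cyclic:
        return period.expected_openings
    k = (date - period.start_date).days % (period.on_days + period.off_days)
    return period.expected_openings if k < period.on_days else 0


def expand_regimen(period: RegimenPeriod) -> dict[dt.date, int]:
    """Map every date of the period to its expected opening count."""
    if (period.on_days is None) != (period.off_days is None):
        raise ScheduleError("On and Off must be both present or both absent")
    return {d: expected_on(period, d)
            for d in date_range(period.start_date, period.end_date)}


def build_schedule(window: MonitorWindow,
                   periods: list[RegimenPeriod]) -> dict[dt.date, int]:
    """Expected openings for every day of a monitoring window.

    ``periods`` must belong to the window's (patient, monitor) and — as
    enforced by cross-reference validation — cover every window day
    exactly once. Periods extending beyond the window are truncated; a
    cyclic period starting before the window keeps its own anchor, so the
    window can begin mid-cycle.
    """
    schedule: dict[dt.date, int] = {}
    for period in periods:
        if period.key != window.key:
            raise ScheduleError(
                f"period for {period.key} does not belong to window {window.key}")
        start = max(period.start_date, window.start_date)
        end = min(period.end_date, window.end_date)
        for d in date_range(start, end):
            if d in schedule:
                raise ScheduleError(f"overlapping regimen periods at {d}")
            schedule[d] = expected_on(period, d)
    for d in date_range(window.start_date, window.end_date):
        if d not in schedule:
            raise ScheduleError(f"no regimen covers {d}")
    return dict(sorted(schedule.items()))
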