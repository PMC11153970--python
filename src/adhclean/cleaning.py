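"""Corrected per-day opening ledger: adjustments, censoring, truncation.

Cleaning turns raw per-day opening counts into the corrected ledger the
implementation statistic is computed from:

* *adjustments* (``AddedOpenings`` rows) add pocket doses or remove
  documented extra openings: ``corrected = max(0, recorded + delta)``;
* *censoring* (``NonMonitoredPeriods`` rows) flags days on which the EM
  was not in use, so no implementation value is computed for them;
* the ledger is truncated to the monitoring window.

The pipeline never infers deviations from opening patterns: pocket doses,
curiosity checks and nonuse periods must be patient-reported, pill-count
validated and entered in the auxiliary workbook by the investigator. In
particular, doses prepared in advance for the next day are handled by the
investigator recording that next day as a nonmonitored period.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from . import validation as V
from .aux_schema import MonitorWindow, NonMonitoredPeriod, OpeningAdjustment
from .dates import date_range
from .validation import ValidationReport


@dataclass
class DailyRecord:
    """Ledger entry for one monitor-day.

    ``implementation`` is filled later (``None`` = not yet computed or
    censored); censoring wins over adjustments on the same day — the
    delta is still recorded but the day contributes to no rate.
    """

    patient_code: str
    monitor: str
    date: dt.date
    expected: int
    recorded: int
    adjustment: int
    corrected: int
    monitored: bool
    implementation: int | None = None


def apply_adjustments(recorded: dict[dt.date, int],
                      adjustments: list[OpeningAdjustment],
                      window: MonitorWindow,
                      report: ValidationReport) -> dict[dt.date, int]:
    """Net adjustment delta per window day; out-of-window rows warn and drop."""
    deltas: dict[dt.date, int] = {}
    for adj in adjustments:
        if adj.date not in window:
            report.warning(V.ADJUST_OUT_OF_WINDOW, "AddedOpenings", adj.row,
                           f"adjustment on {adj.date} outside monitoring window "
                           f"{window.start_date}..{window.end_date}; ignored")
            continue
        deltas[adj.date] = deltas.get(adj.date, 0) + adj.openings_delta
    return deltas


def censored_days(nmps: list[NonMonitoredPeriod],
                  window: MonitorWindow,
                  report: ValidationReport) -> set[dt.date]:
    """Union of nonmonitored days clipped to the window (with warnings)."""
    censored: set[dt.date] = set()
    for nmp in nmps:
        start = max(nmp.start_date, window.start_date)
        end = min(nmp.end_date, window.end_date)
        if start > end:
            report.warning(V.NMP_OUT_OF_WINDOW, "NonMonitoredPeriods", nmp.row,
                           f"period {nmp.start_date}..{nmp.end_date} entirely "
                           f"outside monitoring window; no effect")
            continue
        if start != nmp.start_date or end != nmp.end_date:
            report.warning(V.NMP_CLIPPED, "NonMonitoredPeriods", nmp.row,
                           f"period {nmp.start_date}..{nmp.end_date} clipped to "
                           f"monitoring window {start}..{end}")
        censored.update(date_range(start, end))
    return censored


def build_ledger(window: MonitorWindow,
                 schedule: dict[dt.date, int],
                 recorded: dict[dt.date, int],
                 adjustments: list[OpeningAdjustment],
                 nmps: list[NonMonitoredPeriod],
                 report: ValidationReport,
                 corrections: bool = True) -> list[DailyRecord]:
    """One :class:`DailyRecord` per window day, in date order.

    Days without raw events count as 0 recorded openings. With
    ``corrections=False`` (the "raw" before-cleaning view) adjustments
    and censoring are disabled; schedule and window truncation still
    apply.
    """
    deltas = apply_adjustments(recorded, adjustments, window, report) if corrections else {}
    censored = censored_days(nmps, window, report) if corrections else set()
    ledger: list[DailyRecord] = []
    for d in date_range(window.start_date, window.end_date):
        rec = recorded.get(d, 0)
        delta = deltas.get(d, 0)
        corrected = rec + delta
        if corrected < 0:
            report.warning(V.NEGATIVE_CLAMP, "AddedOpenings", None,
                           f"({window.patient_code}, {window.monitor}) {d}: "
                           f"corrected count {corrected} clamped to 0")
            corrected = 0
        ledger.append(DailyRecord(
            patient_code=window.patient_code,
            monitor=window.monitor,
            date=d,
            expected=schedule[d],
            recorded=rec,
            adjustment=delta,
            corrected=corrected,
            monitored=d not in censored,
        ))
    return ledger
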