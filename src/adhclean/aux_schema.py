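"""Auxiliary Data workbook: parsing, validation and writing.

The Auxiliary Data workbook is the investigator-curated companion to the
raw electronic-monitor (EM) files. Two sheets are mandatory — ``EMInfo``
(one row per EM: patient, monitor, start/end of use) and ``Regimen`` (one
row per regimen period: expected openings/day, optionally a cyclic On/Off
scheme) — and five are optional: ``PatientCovariables``, ``EMCovariables``,
``AddedOpenings`` (signed per-day opening corrections: pocket doses and
extra-opening deletions), ``NonMonitoredPeriods`` (censoring intervals) and
``AdverseEvents``. Sheet and column names are case-sensitive; unknown extra
columns are ignored except in the two covariable sheets, whose columns are
carried verbatim into the output.

Structural problems that would corrupt the implementation calculation
(missing sheets/columns, unparseable dates, orphan rows, regimen coverage
gaps or overlaps) are critical errors; consistency issues that merely
deserve review are warnings. See :mod:`adhclean.validation`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from openpyxl import Workbook

from . import validation as V
from ._xlsx import append_row, save_workbook
from .dates import coerce_date, coerce_id, coerce_int, date_range, is_missing
from .validation import ValidationReport

SHEET_EMINFO = "EMInfo"
SHEET_REGIMEN = "Regimen"
SHEET_PATIENT_COV = "PatientCovariables"
SHEET_EM_COV = "EMCovariables"
SHEET_ADDED = "AddedOpenings"
SHEET_NMP = "NonMonitoredPeriods"
SHEET_AE = "AdverseEvents"

MANDATORY_SHEETS = (SHEET_EMINFO, SHEET_REGIMEN)
OPTIONAL_SHEETS = (SHEET_PATIENT_COV, SHEET_EM_COV, SHEET_ADDED, SHEET_NMP, SHEET_AE)


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonitorWindow:
    """One EM's monitored interval for one patient (an ``EMInfo`` row).

    The cleaned data set is truncated to [start_date, end_date], both ends
    inclusive.
    """

    patient_code: str
    monitor: str
    start_date: dt.date
    end_date: dt.date
    row: int | None = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_code, self.monitor)

    @property
    def length_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def __contains__(self, date: dt.date) -> bool:
        return self.start_date <= date <= self.end_date


@dataclass(frozen=True)
class RegimenPeriod:
    """Expected daily openings over an interval, optionally cyclic.

    A continuous regimen (``on_days``/``off_days`` absent) expects
    ``expected_openings`` every day. A cyclic regimen starts with
    ``on_days`` days at ``expected_openings``, followed by ``off_days``
    days at 0, the cycle anchored at ``start_date``.
    """

    patient_code: str
    monitor: str
    expected_openings: int
    start_date: dt.date
    end_date: dt.date
    on_days: int | None = None
    off_days: int | None = None
    row: int | None = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_code, self.monitor)

    @property
    def cyclic(self) -> bool:
        return self.on_days is not None


@dataclass(frozen=True)
class OpeningAdjustment:
    """Signed per-day opening correction (an ``AddedOpenings`` row).

    Positive deltas insert pocket doses (doses taken without opening the
    EM); negative deltas delete documented extra openings (curiosity
    checks, pharmacist pill counts).
    """

    patient_code: str
    monitor: str
    date: dt.date
    openings_delta: int
    row: int | None = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_code, self.monitor)


@dataclass(frozen=True)
class NonMonitoredPeriod:
    """Interval during which the EM was not used; censored from analysis."""

    patient_code: str
    monitor: str
    start_date: dt.date
    end_date: dt.date
    row: int | None = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_code, self.monitor)


@dataclass(frozen=True)
class AdverseEventRecord:
    """Descriptive adverse-event entry; enrichment only, no effect on rates."""

    patient_code: str
    date: dt.date
    event: str
    grade: str = ""
    row: int | None = field(default=None, compare=False)


@dataclass
class AuxiliaryData:
    """Typed content of one Auxiliary Data workbook."""

    windows: list[MonitorWindow] = field(default_factory=list)
    regimens: list[RegimenPeriod] = field(default_factory=list)
    adjustments: list[OpeningAdjustment] = field(default_factory=list)
    nonmonitored: list[NonMonitoredPeriod] = field(default_factory=list)
    patient_covariables: pd.DataFrame | None = None
    monitor_covariables: pd.DataFrame | None = None
    adverse_events: list[AdverseEventRecord] = field(default_factory=list)

    @property
    def monitors(self) -> set[tuple[str, str]]:
        return {w.key for w in self.windows}

    @property
    def patients(self) -> set[str]:
        return {w.patient_code for w in self.windows}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _read_sheets(path: str | Path) -> dict[str, pd.DataFrame]:
    return pd.read_excel(path, sheet_name=None, dtype=object, engine="openpyxl")


def _has_columns(df: pd.DataFrame, cols: tuple[str, ...], sheet: str,
                 report: ValidationReport) -> bool:
    ok = True
    for col in cols:
        if col not in df.columns:
            report.error(V.MISSING_COLUMN, sheet, 1, f"mandatory column {col!r} missing")
            ok = False
    return ok


def _cell_id(df_row, col, sheet, row, report):
    value = df_row[col]
    if is_missing(value):
        report.error(V.BAD_VALUE, sheet, row, f"{col} is missing")
        return None
    try:
        return coerce_id(value)
    except ValueError as exc:
        report.error(V.BAD_VALUE, sheet, row, f"{col}: {exc}")
        return None


def _cell_date(df_row, col, sheet, row, report):
    value = df_row[col]
    if is_missing(value):
        report.error(V.BAD_DATE, sheet, row, f"{col} is missing")
        return None
    try:
        return coerce_date(value)
    except ValueError as exc:
        report.error(V.BAD_DATE, sheet, row, f"{col}: {exc}")
        return None


def _parse_eminfo(df: pd.DataFrame, report: ValidationReport) -> list[MonitorWindow]:
    if not _has_columns(df, ("PatientCode", "Monitor", "StartDate", "EndDate"),
                        SHEET_EMINFO, report):
        return []
    windows: list[MonitorWindow] = []
    seen: set[tuple[str, str]] = set()
    for i, (_, r) in enumerate(df.iterrows()):
        row = i + 2
        patient = _cell_id(r, "PatientCode", SHEET_EMINFO, row, report)
        monitor = _cell_id(r, "Monitor", SHEET_EMINFO, row, report)
        start = _cell_date(r, "StartDate", SHEET_EMINFO, row, report)
        end = _cell_date(r, "EndDate", SHEET_EMINFO, row, report)
        if None in (patient, monitor, start, end):
            continue
        if start > end:
            report.error(V.DATE_ORDER, SHEET_EMINFO, row,
                         f"StartDate {start} after EndDate {end}")
            continue
        if (patient, monitor) in seen:
            report.error(V.DUPLICATE_MONITOR, SHEET_EMINFO, row,
                         f"duplicate EMInfo entry for ({patient}, {monitor})")
            continue
        seen.add((patient, monitor))
        windows.append(MonitorWindow(patient, monitor, start, end, row=row))
    return windows


def _parse_regimen(df: pd.DataFrame, report: ValidationReport) -> list[RegimenPeriod]:
    if not _has_columns(df, ("PatientCode", "Monitor", "ExpectedOpenings",
                             "StartDate", "EndDate"), SHEET_REGIMEN, report):
        return []
    periods: list[RegimenPeriod] = []
    for i, (_, r) in enumerate(df.iterrows()):
        row = i + 2
        patient = _cell_id(r, "PatientCode", SHEET_REGIMEN, row, report)
        monitor = _cell_id(r, "Monitor", SHEET_REGIMEN, row, report)
        start = _cell_date(r, "StartDate", SHEET_REGIMEN, row, report)
        end = _cell_date(r, "EndDate", SHEET_REGIMEN, row, report)
        expected = None
        if not is_missing(r["ExpectedOpenings"]):
            try:
                expected = coerce_int(r["ExpectedOpenings"])
                if expected < 0:
                    raise ValueError("must be nonnegative")
            except ValueError as exc:
                report.error(V.BAD_VALUE, SHEET_REGIMEN, row, f"ExpectedOpenings: {exc}")
                expected = None
        else:
            report.error(V.BAD_VALUE, SHEET_REGIMEN, row, "ExpectedOpenings is missing")

        on_raw = r["On"] if "On" in df.columns else None
        off_raw = r["Off"] if "Off" in df.columns else None
        on = off = None
        bad_cycle = False
        if is_missing(on_raw) != is_missing(off_raw):
            report.error(V.ON_OFF_PAIR, SHEET_REGIMEN, row,
                         "On and Off must be filled together or both left blank")
            bad_cycle = True
        elif not is_missing(on_raw):
            try:
                on = coerce_int(on_raw)
                off = coerce_int(off_raw)
                if on <= 0 or off <= 0:
                    raise ValueError("On/Off must be positive integers")
            except ValueError as exc:
                report.error(V.BAD_VALUE, SHEET_REGIMEN, row, f"On/Off: {exc}")
                bad_cycle = True

        if None in (patient, monitor, start, end) or expected is None or bad_cycle:
            continue
        if start > end:
            report.error(V.DATE_ORDER, SHEET_REGIMEN, row,
                         f"StartDate {start} after EndDate {end}")
            continue
        periods.append(RegimenPeriod(patient, monitor, expected, start, end,
                                     on, off, row=row))
    return periods


def _parse_added(df: pd.DataFrame, report: ValidationReport) -> list[OpeningAdjustment]:
    if not _has_columns(df, ("PatientCode", "Monitor", "Date", "Openings"),
                        SHEET_ADDED, report):
        return []
    out: list[OpeningAdjustment] = []
    for i, (_, r) in enumerate(df.iterrows()):
        row = i + 2
        patient = _cell_id(r, "PatientCode", SHEET_ADDED, row, report)
        monitor = _cell_id(r, "Monitor", SHEET_ADDED, row, report)
        date = _cell_date(r, "Date", SHEET_ADDED, row, report)
        delta = None
        if is_missing(r["Openings"]):
            report.error(V.BAD_VALUE, SHEET_ADDED, row, "Openings is missing")
        else:
            try:
                delta = coerce_int(r["Openings"])
            except ValueError as exc:
                report.error(V.BAD_VALUE, SHEET_ADDED, row, f"Openings: {exc}")
        if None in (patient, monitor, date) or delta is None:
            continue
        if delta == 0:
            report.warning(V.ZERO_DELTA, SHEET_ADDED, row,
                           "Openings delta of 0 has no effect; row ignored")
            continue
        out.append(OpeningAdjustment(patient, monitor, date, delta, row=row))
    return out


def _parse_nmp(df: pd.DataFrame, report: ValidationReport) -> list[NonMonitoredPeriod]:
    if not _has_columns(df, ("PatientCode", "Monitor", "StartDate", "EndDate"),
                        SHEET_NMP, report):
        return []
    out: list[NonMonitoredPeriod] = []
    for i, (_, r) in enumerate(df.iterrows()):
        row = i + 2
        patient = _cell_id(r, "PatientCode", SHEET_NMP, row, report)
        monitor = _cell_id(r, "Monitor", SHEET_NMP, row, report)
        start = _cell_date(r, "StartDate", SHEET_NMP, row, report)
        end = _cell_date(r, "EndDate", SHEET_NMP, row, report)
        if None in (patient, monitor, start, end):
            continue
        if start > end:
            report.error(V.DATE_ORDER, SHEET_NMP, row,
                         f"StartDate {start} after EndDate {end}")
            continue
        out.append(NonMonitoredPeriod(patient, monitor, start, end, row=row))
    return out


def _parse_adverse(df: pd.DataFrame, report: ValidationReport) -> list[AdverseEventRecord]:
    if not _has_columns(df, ("PatientCode", "Date", "Event"), SHEET_AE, report):
        return []
    out: list[AdverseEventRecord] = []
    for i, (_, r) in enumerate(df.iterrows()):
        row = i + 2
        patient = _cell_id(r, "PatientCode", SHEET_AE, row, report)
        date = _cell_date(r, "Date", SHEET_AE, row, report)
        event = "" if is_missing(r["Event"]) else str(r["Event"]).strip()
        grade_raw = r["Grade"] if "Grade" in df.columns else None
        grade = "" if is_missing(grade_raw) else str(grade_raw).strip()
        if None in (patient, date):
            continue
        out.append(AdverseEventRecord(patient, date, event, grade, row=row))
    return out


def _parse_covariables(df: pd.DataFrame, sheet: str, keys: tuple[str, ...],
                       report: ValidationReport) -> pd.DataFrame | None:
    if not _has_columns(df, keys, sheet, report):
        return None
    df = df.copy()
    for i in range(len(df)):
        for col in keys:
            value = df.iloc[i][col]
            if is_missing(value):
                report.error(V.BAD_VALUE, sheet, i + 2, f"{col} is missing")
            else:
                try:
                    df.iloc[i, df.columns.get_loc(col)] = coerce_id(value)
                except ValueError as exc:
                    report.error(V.BAD_VALUE, sheet, i + 2, f"{col}: {exc}")
    return df


def load_auxiliary(workbook_path: str | Path) -> tuple[AuxiliaryData, ValidationReport]:
    """Parse and validate one Auxiliary Data workbook.

    Returns the typed collections plus a :class:`ValidationReport`; a row
    that fails validation is reported and excluded from the collections.
    Cross-sheet consistency (orphan rows, regimen coverage) is checked
    separately by :func:`validate_cross_references` once the raw-data
    folder has been scanned.
    """
    report = ValidationReport()
    aux = AuxiliaryData()
    try:
        sheets = _read_sheets(workbook_path)
    except Exception as exc:  # unreadable workbook
        report.error(V.UNREADABLE_FILE, str(workbook_path), None,
                     f"cannot read workbook: {exc}")
        return aux, report

    for name in MANDATORY_SHEETS:
        if name not in sheets:
            report.error(V.MISSING_SHEET, name, None, f"mandatory sheet {name!r} missing")
    if SHEET_EMINFO in sheets:
        aux.windows = _parse_eminfo(sheets[SHEET_EMINFO], report)
    if SHEET_REGIMEN in sheets:
        aux.regimens = _parse_regimen(sheets[SHEET_REGIMEN], report)
    if SHEET_ADDED in sheets:
        aux.adjustments = _parse_added(sheets[SHEET_ADDED], report)
    if SHEET_NMP in sheets:
        aux.nonmonitored = _parse_nmp(sheets[SHEET_NMP], report)
    if SHEET_AE in sheets:
        aux.adverse_events = _parse_adverse(sheets[SHEET_AE], report)
    if SHEET_PATIENT_COV in sheets:
        aux.patient_covariables = _parse_covariables(
            sheets[SHEET_PATIENT_COV], SHEET_PATIENT_COV, ("PatientCode",), report)
    if SHEET_EM_COV in sheets:
        aux.monitor_covariables = _parse_covariables(
            sheets[SHEET_EM_COV], SHEET_EM_COV, ("PatientCode", "Monitor"), report)
    return aux, report


# ---------------------------------------------------------------------------
# cross-reference validation
# ---------------------------------------------------------------------------

def _runs(dates: list[dt.date]) -> list[tuple[dt.date, dt.date]]:
    """Collapse a sorted date list into contiguous [start, end] runs."""
    runs: list[tuple[dt.date, dt.date]] = []
    for d in dates:
        if runs and (d - runs[-1][1]).days == 1:
            runs[-1] = (runs[-1][0], d)
        else:
            runs.append((d, d))
    return runs


def validate_cross_references(aux: AuxiliaryData,
                              monitors_seen_in_raw: set[tuple[str, str]],
                              ) -> ValidationReport:
    """Consistency checks across sheets and against the raw-data folder.

    Critical: auxiliary rows referencing a (patient, monitor) absent from
    ``EMInfo`` (``ORPHAN_ROW``); monitoring-window days covered by zero
    (``REGIMEN_GAP``) or more than one (``REGIMEN_OVERLAP``) regimen
    period. Warnings: declared monitors with no raw events
    (``NO_RAW_DATA``); raw events for undeclared monitors
    (``UNDECLARED_MONITOR`` — those events are excluded from output).
    """
    report = ValidationReport()
    declared = aux.monitors

    for window in aux.windows:
        if window.key not in monitors_seen_in_raw:
            report.warning(V.NO_RAW_DATA, SHEET_EMINFO, window.row,
                           f"no raw EM data found for ({window.patient_code}, "
                           f"{window.monitor})")
    for key in sorted(monitors_seen_in_raw - declared):
        report.warning(V.UNDECLARED_MONITOR, "raw data", None,
                       f"raw events for ({key[0]}, {key[1]}) not declared in "
                       f"EMInfo; events excluded")

    for coll, sheet in ((aux.regimens, SHEET_REGIMEN),
                        (aux.adjustments, SHEET_ADDED),
                        (aux.nonmonitored, SHEET_NMP)):
        for rec in coll:
            if rec.key not in declared:
                report.error(V.ORPHAN_ROW, sheet, rec.row,
                             f"({rec.patient_code}, {rec.monitor}) not declared "
                             f"in EMInfo")

    if aux.monitor_covariables is not None:
        for i, (_, r) in enumerate(aux.monitor_covariables.iterrows()):
            if (str(r["PatientCode"]), str(r["Monitor"])) not in declared:
                report.warning(V.UNKNOWN_KEY, SHEET_EM_COV, i + 2,
                               "key not declared in EMInfo")
    patients = aux.patients
    if aux.patient_covariables is not None:
        for i, (_, r) in enumerate(aux.patient_covariables.iterrows()):
            if str(r["PatientCode"]) not in patients:
                report.warning(V.UNKNOWN_KEY, SHEET_PATIENT_COV, i + 2,
                               "PatientCode not declared in EMInfo")
    for ae in aux.adverse_events:
        if ae.patient_code not in patients:
            report.warning(V.UNKNOWN_KEY, SHEET_AE, ae.row,
                           "PatientCode not declared in EMInfo")

    # every window day must be covered by exactly one regimen period
    periods_by_key: dict[tuple[str, str], list[RegimenPeriod]] = {}
    for p in aux.regimens:
        periods_by_key.setdefault(p.key, []).append(p)
    for window in aux.windows:
        periods = periods_by_key.get(window.key, [])
        gaps, overlaps = [], []
        for d in date_range(window.start_date, window.end_date):
            n = sum(1 for p in periods if p.start_date <= d <= p.end_date)
            if n == 0:
                gaps.append(d)
            elif n > 1:
                overlaps.append(d)
        for a, b in _runs(gaps):
            report.error(V.REGIMEN_GAP, SHEET_REGIMEN, None,
                         f"({window.patient_code}, {window.monitor}): no regimen "
                         f"covers {a}..{b}")
        for a, b in _runs(overlaps):
            report.error(V.REGIMEN_OVERLAP, SHEET_REGIMEN, None,
                         f"({window.patient_code}, {window.monitor}): multiple "
                         f"regimen periods cover {a}..{b}")
    return report


# ---------------------------------------------------------------------------
# writing (round-trip support and fixture construction)
# ---------------------------------------------------------------------------

def write_auxiliary(aux: AuxiliaryData, path: str | Path) -> None:
    """Write an :class:`AuxiliaryData` back to a workbook.

    Re-loading the written file yields identical records field-by-field.
    Empty optional collections produce no sheet. Output is byte-for-byte
    deterministic for identical content.
    """
    wb = Workbook()
    ws = wb.active
    ws.title = SHEET_EMINFO
    ws.append(["PatientCode", "Monitor", "StartDate", "EndDate"])
    for w in aux.windows:
        append_row(ws, [w.patient_code, w.monitor, w.start_date, w.end_date], {3, 4})

    ws = wb.create_sheet(SHEET_REGIMEN)
    ws.append(["PatientCode", "Monitor", "ExpectedOpenings", "StartDate", "EndDate",
               "On", "Off"])
    for p in aux.regimens:
        append_row(ws, [p.patient_code, p.monitor, p.expected_openings,
                        p.start_date, p.end_date, p.on_days, p.off_days], {4, 5})

    if aux.patient_covariables is not None:
        ws = wb.create_sheet(SHEET_PATIENT_COV)
        ws.append(list(aux.patient_covariables.columns))
        for _, r in aux.patient_covariables.iterrows():
            ws.append(list(r))
    if aux.monitor_covariables is not None:
        ws = wb.create_sheet(SHEET_EM_COV)
        ws.append(list(aux.monitor_covariables.columns))
        for _, r in aux.monitor_covariables.iterrows():
            ws.append(list(r))
    if aux.adjustments:
        ws = wb.create_sheet(SHEET_ADDED)
        ws.append(["PatientCode", "Monitor", "Date", "Openings"])
        for a in aux.adjustments:
            append_row(ws, [a.patient_code, a.monitor, a.date, a.openings_delta], {3})
    if aux.nonmonitored:
        ws = wb.create_sheet(SHEET_NMP)
        ws.append(["PatientCode", "Monitor", "StartDate", "EndDate"])
        for n in aux.nonmonitored:
            append_row(ws, [n.patient_code, n.monitor, n.start_date, n.end_date], {3, 4})
    if aux.adverse_events:
        ws = wb.create_sheet(SHEET_AE)
        ws.append(["PatientCode", "Date", "Event", "Grade"])
        for e in aux.adverse_events:
            append_row(ws, [e.patient_code, e.date, e.event, e.grade], {2})
    save_workbook(wb, path)
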