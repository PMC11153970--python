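"""Raw electronic-monitor file ingestion.

Raw EM exports live together in one folder; a file participates when its
basename contains the substring ``eventslist``. Two layouts are accepted
and auto-detected by header:

* *events*: one row per EM opening, columns ``PatientCode``, ``Monitor``,
  ``Date`` (date-time or date string) — the native export of MEMS-style
  monitor software;
* *daily adherence*: one row per day with an extra ``RecordedOpenings``
  count column.

Either way ingestion reduces to per-day opening counts per
(patient, monitor). One file may contain several patients' data.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import validation as V
from .dates import coerce_date, coerce_id, coerce_int, coerce_timestamp, is_missing
from .validation import ValidationReport

FILENAME_TOKEN = "eventslist"
_EXTENSIONS = {".csv", ".txt", ".tsv", ".xlsx", ".xls"}
_REQUIRED = ("PatientCode", "Monitor", "Date")


@dataclass(frozen=True)
class RawEvent:
    """One EM opening: the monitor's proxy for one medication intake."""

    patient_code: str
    monitor: str
    timestamp: dt.datetime


@dataclass(frozen=True)
class DailyOpenings:
    """Recorded opening count for one (patient, monitor, calendar day)."""

    patient_code: str
    monitor: str
    date: dt.date
    recorded: int


def discover_raw_files(folder: str | Path) -> tuple[list[Path], ValidationReport]:
    """List raw EM files in ``folder`` (basename contains ``eventslist``).

    Non-matching visible files draw an ``IGNORED_FILE`` warning; an empty
    result is the critical error ``NO_RAW_FILES``.
    """
    report = ValidationReport()
    folder = Path(folder)
    matches: list[Path] = []
    for path in sorted(folder.iterdir()):
        if not path.is_file() or path.name.startswith((".", "~$")):
            continue
        if FILENAME_TOKEN in path.name and path.suffix.lower() in _EXTENSIONS:
            matches.append(path)
        else:
            report.warning(V.IGNORED_FILE, path.name, None,
                           f"filename does not contain {FILENAME_TOKEN!r}; ignored")
    if not matches:
        report.error(V.NO_RAW_FILES, str(folder), None,
                     f"no raw EM file (filename containing {FILENAME_TOKEN!r}) found")
    return matches, report


def _read_table(path: Path) -> pd.DataFrame:
    """Load a delimited or Excel raw file, sniffing , ; and tab delimiters."""
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=object, engine="openpyxl")
    last = None
    for sep in (",", ";", "\t"):
        try:
            df = pd.read_csv(path, sep=sep, dtype=object)
        except Exception as exc:  # pragma: no cover - malformed text
            last = exc
            continue
        if all(c in df.columns for c in _REQUIRED):
            return df
        last = ValueError(f"required columns {_REQUIRED} not found")
    raise ValueError(f"cannot parse {path.name}: {last}")


def read_events(path: str | Path
                ) -> tuple[list[RawEvent] | list[DailyOpenings], ValidationReport]:
    """Parse one raw file into events or daily counts (auto-detected).

    The daily-adherence layout is recognised by the presence of a
    ``RecordedOpenings`` column. Exactly duplicated event rows are kept
    as distinct openings (monitors can log rapid successive openings)
    with a ``DUPLICATE_EVENT`` warning.
    """
    report = ValidationReport()
    path = Path(path)
    try:
        df = _read_table(path)
    except ValueError as exc:
        report.error(V.UNREADABLE_FILE, path.name, None, str(exc))
        return [], report
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        report.error(V.MISSING_COLUMN, path.name, 1,
                     f"missing required column(s): {', '.join(missing)}")
        return [], report

    daily_format = "RecordedOpenings" in df.columns
    out: list = []
    for i, (_, r) in enumerate(df.iterrows()):
        row = i + 2
        try:
            patient = coerce_id(r["PatientCode"])
            monitor = coerce_id(r["Monitor"])
        except ValueError as exc:
            report.error(V.BAD_VALUE, path.name, row, str(exc))
            continue
        if daily_format:
            try:
                date = coerce_date(r["Date"])
            except ValueError as exc:
                report.error(V.BAD_DATE, path.name, row, f"Date: {exc}")
                continue
            if is_missing(r["RecordedOpenings"]):
                report.error(V.BAD_VALUE, path.name, row, "RecordedOpenings is missing")
                continue
            try:
                recorded = coerce_int(r["RecordedOpenings"])
                if recorded < 0:
                    raise ValueError("must be nonnegative")
            except ValueError as exc:
                report.error(V.BAD_VALUE, path.name, row, f"RecordedOpenings: {exc}")
                continue
            out.append(DailyOpenings(patient, monitor, date, recorded))
        else:
            try:
                ts = coerce_timestamp(r["Date"])
            except ValueError as exc:
                report.error(V.BAD_DATE, path.name, row, f"Date: {exc}")
                continue
            out.append(RawEvent(patient, monitor, ts))

    if not daily_format:
        dupes = Counter(out)
        for ev, n in dupes.items():
            if n > 1:
                report.warning(V.DUPLICATE_EVENT, path.name, None,
                               f"{n} identical rows for ({ev.patient_code}, "
                               f"{ev.monitor}) at {ev.timestamp}; all kept")
    return out, report


def aggregate_daily(events: list[RawEvent]) -> list[DailyOpenings]:
    """Count events per (patient, monitor, calendar date).

    Days without events produce no record (downstream treats absence as
    0 recorded openings). Total openings are conserved.
    """
    counts: Counter[tuple[str, str, dt.date]] = Counter()
    for ev in events:
        counts[(ev.patient_code, ev.monitor, ev.timestamp.date())] += 1
    return [DailyOpenings(p, m, d, n) for (p, m, d), n in sorted(counts.items())]


def load_raw_folder(folder: str | Path
                    ) -> tuple[list[DailyOpenings], set[tuple[str, str]], ValidationReport]:
    """Discover, read and aggregate every raw file in ``folder``.

    Returns per-day counts (summed across files when a monitor-day appears
    in more than one file), the set of (patient, monitor) pairs seen, and
    the merged validation report.
    """
    files, report = discover_raw_files(folder)
    counts: Counter[tuple[str, str, dt.date]] = Counter()
    for path in files:
        records, rep = read_events(path)
        report.merge(rep)
        if records and isinstance(records[0], RawEvent):
            records = aggregate_daily(records)  # type: ignore[arg-type]
        for rec in records:  # type: ignore[union-attr]
            counts[(rec.patient_code, rec.monitor, rec.date)] += rec.recorded
    daily = [DailyOpenings(p, m, d, n) for (p, m, d), n in sorted(counts.items())]
    monitors = {(d.patient_code, d.monitor) for d in daily}
    return daily, monitors, report
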