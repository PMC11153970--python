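"""Output rendering: the 4-sheet implementation workbook and the log files.

The workbook holds sheets ``by monitor`` (one row per monitor-day),
``by patient`` (one row per patient-day), ``summary by monitor`` and
``summary by patient``. Censored days are rendered as genuinely empty
implementation cells (not 0 and not the text "NA"). Summary rates are
rendered as percentages with one decimal; day counts and dates are plain
cells. ``errors.log`` and ``warnings.log`` are tab-separated UTF-8 text,
one finding per line, deterministically ordered — identical runs produce
byte-identical files.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd
from openpyxl import Workbook

from ._xlsx import DATE_FORMAT, save_workbook
from .validation import Finding, ValidationReport

SHEET_BY_MONITOR = "by monitor"
SHEET_BY_PATIENT = "by patient"
SHEET_SUMMARY_MONITOR = "summary by monitor"
SHEET_SUMMARY_PATIENT = "summary by patient"


def render_rate(rate) -> float | None:
    """Proportion -> percentage with 1 decimal (None stays empty)."""
    if rate is None or pd.isna(rate):
        return None
    return round(float(rate) * 100, 1)


def _cell(value):
    if value is None or (not isinstance(value, (str, dt.date, dt.datetime))
                         and pd.isna(value)):
        return None
    if isinstance(value, pd.Timestamp):
        return value.to_pydatetime()
    # numpy scalars -> native python for openpyxl
    if hasattr(value, "item"):
        return value.item()
    return value


def _write_frame(ws, df: pd.DataFrame, date_cols: set[str],
                 pct_cols: set[str] = frozenset()) -> None:
    ws.append(list(df.columns))
    date_idx = {i + 1 for i, c in enumerate(df.columns) if c in date_cols}
    for _, r in df.iterrows():
        values = []
        for col in df.columns:
            v = _cell(r[col])
            if col in pct_cols:
                v = render_rate(v)
            values.append(v)
        ws.append(values)
        for ci in date_idx:
            ws.cell(row=ws.max_row, column=ci).number_format = DATE_FORMAT


def write_implementation(workbook_path: str | Path,
                         ledger: pd.DataFrame,
                         pdays: pd.DataFrame,
                         monitor_summary: pd.DataFrame,
                         patient_summary: pd.DataFrame,
                         csv_mirror: bool = False) -> Path:
    """Write the implementation workbook; optionally mirror sheets as CSV.

    Callers must gate on the validation report: the workbook is only
    meaningful when no critical error is outstanding.
    """
    workbook_path = Path(workbook_path)
    wb = Workbook()
    ws = wb.active
    ws.title = SHEET_BY_MONITOR
    _write_frame(ws, ledger, {"Date"})
    _write_frame(wb.create_sheet(SHEET_BY_PATIENT), pdays, {"Date"})
    _write_frame(wb.create_sheet(SHEET_SUMMARY_MONITOR), monitor_summary,
                 {"StartDate", "EndDate"}, {"ImplementationRate"})
    _write_frame(wb.create_sheet(SHEET_SUMMARY_PATIENT), patient_summary,
                 set(), {"ImplementationRate"})
    save_workbook(wb, workbook_path)

    if csv_mirror:
        stem = workbook_path.with_suffix("")
        for name, df, pct in ((SHEET_BY_MONITOR, ledger, set()),
                              (SHEET_BY_PATIENT, pdays, set()),
                              (SHEET_SUMMARY_MONITOR, monitor_summary,
                               {"ImplementationRate"}),
                              (SHEET_SUMMARY_PATIENT, patient_summary,
                               {"ImplementationRate"})):
            out = df.copy()
            for col in pct:
                if col in out.columns:
                    out[col] = out[col].map(render_rate)
            out.to_csv(f"{stem}_{name.replace(' ', '_')}.csv", index=False)
    return workbook_path


def write_logs(report: ValidationReport, folder: str | Path
               ) -> tuple[Path, Path]:
    """Write ``errors.log`` and ``warnings.log`` into ``folder``.

    Both files are always created (possibly empty), findings ordered by
    (location, row, code) so reruns are byte-identical.
    """
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    errors_path = folder / "errors.log"
    warnings_path = folder / "warnings.log"
    _write_log(errors_path, report.sorted_errors())
    _write_log(warnings_path, report.sorted_warnings())
    return errors_path, warnings_path


def _write_log(path: Path, findings: list[Finding]) -> None:
    text = "".join(f.render() + "\n" for f in findings)
    path.write_text(text, encoding="utf-8")
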