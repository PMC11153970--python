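"""End-to-end orchestration: auxiliary workbook + raw folder -> outputs.

``run_pipeline`` wires the modules together: parse and validate the
Auxiliary Data workbook, ingest the raw EM folder, cross-check them,
build expected schedules, clean the per-day ledger, score the daily
implementation statistic, summarise, and (optionally) write the 4-sheet
implementation workbook. The two log files are always written. Output is
gated on validation: any critical error suppresses the workbook.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .aux_schema import (AuxiliaryData, load_auxiliary, validate_cross_references)
from .cleaning import DailyRecord, build_ledger
from .implementation import (ledger_frame, patient_days, score_ledger,
                             summarize_monitors, summarize_patients)
from .raw_ingest import load_raw_folder
from .reporting import write_implementation, write_logs
from .schedule import build_schedule
from .validation import ValidationReport


@dataclass
class PipelineResult:
    """Everything one run produced (frames are empty when output is blocked)."""

    aux: AuxiliaryData
    report: ValidationReport
    ledger: pd.DataFrame = field(default_factory=pd.DataFrame)
    patient_days: pd.DataFrame = field(default_factory=pd.DataFrame)
    monitor_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    patient_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    workbook_path: Path | None = None
    errors_log: Path | None = None
    warnings_log: Path | None = None

    @property
    def ok(self) -> bool:
        return self.report.ok


def compute_ledger(aux: AuxiliaryData,
                   daily,
                   report: ValidationReport,
                   corrections: bool = True) -> list[DailyRecord]:
    """Score every declared monitor's window days (helper for run_pipeline)."""
    recorded: dict[tuple[str, str], dict[dt.date, int]] = {}
    for rec in daily:
        recorded.setdefault((rec.patient_code, rec.monitor), {})[rec.date] = \
            recorded.get((rec.patient_code, rec.monitor), {}).get(rec.date, 0) + rec.recorded

    regimens: dict[tuple[str, str], list] = {}
    for p in aux.regimens:
        regimens.setdefault(p.key, []).append(p)
    adjustments: dict[tuple[str, str], list] = {}
    for a in aux.adjustments:
        adjustments.setdefault(a.key, []).append(a)
    nmps: dict[tuple[str, str], list] = {}
    for n in aux.nonmonitored:
        nmps.setdefault(n.key, []).append(n)

    records: list[DailyRecord] = []
    for window in sorted(aux.windows, key=lambda w: w.key):
        periods = sorted(regimens.get(window.key, []), key=lambda p: p.start_date)
        schedule = build_schedule(window, periods)
        records.extend(build_ledger(
            window, schedule,
            recorded.get(window.key, {}),
            adjustments.get(window.key, []),
            nmps.get(window.key, []),
            report, corrections=corrections))
    return score_ledger(records)


def run_pipeline(aux_workbook: str | Path,
                 raw_folder: str | Path,
                 out: str | Path | None = None,
                 corrections: bool = True,
                 csv_mirror: bool = False,
                 strict: bool = False,
                 log_folder: str | Path | None = None) -> PipelineResult:
    """Run the full cleaning pipeline.

    Parameters
    ----------
    aux_workbook, raw_folder
        The Auxiliary Data workbook and the folder of raw EM files.
    out
        Path for the implementation workbook; ``None`` computes results
        in memory without writing it.
    corrections
        ``False`` disables adjustments and censoring (the "raw",
        before-cleaning view used for before/after comparisons); window
        truncation and schedules still apply.
    csv_mirror
        Also write each workbook sheet as a CSV next to ``out``.
    strict
        Promote every warning to a critical (blocking) error.
    log_folder
        Where ``errors.log``/``warnings.log`` go; defaults to the
        auxiliary workbook's folder.
    """
    aux_workbook = Path(aux_workbook)
    log_folder = Path(log_folder) if log_folder is not None else aux_workbook.parent

    aux, report = load_auxiliary(aux_workbook)
    daily, monitors_seen, raw_report = load_raw_folder(raw_folder)
    report.merge(raw_report)
    report.merge(validate_cross_references(aux, monitors_seen))
    if strict:
        report.promote_warnings()

    result = PipelineResult(aux=aux, report=report)
    if not report.ok:
        result.errors_log, result.warnings_log = write_logs(report, log_folder)
        return result

    declared = aux.monitors
    daily = [d for d in daily if (d.patient_code, d.monitor) in declared]
    records = compute_ledger(aux, daily, report, corrections=corrections)

    result.ledger = ledger_frame(records)
    result.patient_days = patient_days(result.ledger)
    result.monitor_summary = summarize_monitors(
        result.ledger, aux.windows, aux.monitor_covariables, report)
    result.patient_summary = summarize_patients(
        result.patient_days, aux.patient_covariables, report)

    if out is not None:
        result.workbook_path = write_implementation(
            out, result.ledger, result.patient_days,
            result.monitor_summary, result.patient_summary,
            csv_mirror=csv_mirror)
    result.errors_log, result.warnings_log = write_logs(report, log_folder)
    return result
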