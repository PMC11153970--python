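"""The daily binary implementation statistic and its summaries.

Implementation — the extent to which dosing matches the prescribed
regimen while on treatment — is scored per monitor-day:

* 1 (optimal) when corrected openings >= expected openings. This is the
  full rule: days with 0 expected openings (the Off phase of a cyclic
  regimen) are trivially optimal, and overconsumption is not penalised.
* 0 (suboptimal) otherwise.
* NA when the day is censored (nonmonitored period) — the day enters
  neither numerator nor denominator.

Per patient-day the statistic is the product over all monitors whose
window covers that day: one suboptimal monitor makes the day suboptimal;
one censored monitor censors the day. The summary rate at either level is
optimal days / monitored days.
"""

from __future__ import annotations

import pandas as pd

from . import validation as V
from .cleaning import DailyRecord
from .validation import ValidationReport

LEDGER_COLUMNS = ["PatientCode", "Monitor", "Date", "ExpectedOpenings",
                  "RecordedOpenings", "AddedOpenings", "CorrectedOpenings",
                  "Monitored", "Implementation"]


def daily_implementation(record: DailyRecord) -> int | None:
    """Score one monitor-day: NA if censored, else corrected >= expected."""
    if not record.monitored:
        return None
    return 1 if record.corrected >= record.expected else 0


def score_ledger(records: list[DailyRecord]) -> list[DailyRecord]:
    """Fill ``implementation`` in place for every record; returns the list."""
    for rec in records:
        rec.implementation = daily_implementation(rec)
    return records


def ledger_frame(records: list[DailyRecord]) -> pd.DataFrame:
    """Scored ledger as a DataFrame (Implementation is nullable Int64)."""
    df = pd.DataFrame(
        [(r.patient_code, r.monitor, r.date, r.expected, r.recorded,
          r.adjustment, r.corrected, r.monitored, r.implementation)
         for r in records],
        columns=LEDGER_COLUMNS)
    df["Implementation"] = df["Implementation"].astype("Int64")
    return df


def patient_days(ledger: pd.DataFrame) -> pd.DataFrame:
    """Combine per-monitor days into per-patient days (product rule).

    Scope on a given date is the set of monitors whose window contains
    the date, i.e. exactly the ledger rows for that (patient, date). The
    day is NA when any in-scope monitor is censored, 0 when any scores 0,
    else 1. ``MonitorsInScope`` counts the contributing monitors.
    """
    rows = []
    if len(ledger):
        for (patient, date), grp in ledger.groupby(["PatientCode", "Date"], sort=True):
            vals = grp["Implementation"]
            if vals.isna().any():
                impl = pd.NA
            else:
                impl = int(vals.min())  # product of 0/1 values
            rows.append((patient, date, len(grp), impl))
    df = pd.DataFrame(rows, columns=["PatientCode", "Date", "MonitorsInScope",
                                     "Implementation"])
    df["Implementation"] = df["Implementation"].astype("Int64")
    return df


def _rate(optimal: int, monitored: int) -> float | None:
    return optimal / monitored if monitored else None


def summarize_monitors(ledger: pd.DataFrame,
                       windows,
                       monitor_covariables: pd.DataFrame | None,
                       report: ValidationReport) -> pd.DataFrame:
    """Per-monitor summary: monitored/optimal days and implementation rate.

    Nonmonitored (NA) days are excluded from both numerator and
    denominator; EM covariables are joined by (PatientCode, Monitor).
    A monitor with zero monitored days gets an empty rate and a warning.
    """
    rows = []
    by_key = {w.key: w for w in windows}
    if len(ledger):
        for (patient, monitor), grp in ledger.groupby(["PatientCode", "Monitor"],
                                                      sort=True):
            vals = grp["Implementation"]
            monitored = int(vals.notna().sum())
            optimal = int((vals == 1).sum())
            if monitored == 0:
                report.warning(V.ZERO_DENOMINATOR, "summary by monitor", None,
                               f"({patient}, {monitor}): no monitored days; "
                               f"rate undefined")
            w = by_key.get((patient, monitor))
            rows.append((patient, monitor,
                         w.start_date if w else None, w.end_date if w else None,
                         monitored, optimal, _rate(optimal, monitored)))
    df = pd.DataFrame(rows, columns=["PatientCode", "Monitor", "StartDate",
                                     "EndDate", "MonitoredDays", "OptimalDays",
                                     "ImplementationRate"])
    if monitor_covariables is not None and len(df):
        extra = monitor_covariables.drop_duplicates(["PatientCode", "Monitor"])
        df = df.merge(extra, on=["PatientCode", "Monitor"], how="left")
    return df


def summarize_patients(pdays: pd.DataFrame,
                       patient_covariables: pd.DataFrame | None,
                       report: ValidationReport) -> pd.DataFrame:
    """Per-patient summary over patient-days; joins patient covariables."""
    rows = []
    if len(pdays):
        for patient, grp in pdays.groupby("PatientCode", sort=True):
            vals = grp["Implementation"]
            monitored = int(vals.notna().sum())
            optimal = int((vals == 1).sum())
            if monitored == 0:
                report.warning(V.ZERO_DENOMINATOR, "summary by patient", None,
                               f"{patient}: no monitored days; rate undefined")
            rows.append((patient, monitored, optimal, _rate(optimal, monitored)))
    df = pd.DataFrame(rows, columns=["PatientCode", "MonitoredDays",
                                     "OptimalDays", "ImplementationRate"])
    if patient_covariables is not None and len(df):
        extra = patient_covariables.drop_duplicates(["PatientCode"])
        df = df.merge(extra, on="PatientCode", how="left")
    return df
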