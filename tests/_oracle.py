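"""Independent brute-force recomputation of the implementation statistic.

Deliberately shares no code with the package: the auxiliary workbook is
read cell-by-cell with openpyxl, raw files with the csv module, and every
quantity is recomputed by day-by-day enumeration with plain dicts. Used
to cross-check the pipeline on small fixtures.
"""

from __future__ import annotations

import csv
import datetime as dt
from pathlib import Path

from openpyxl import load_workbook


def _d(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.datetime.fromisoformat(str(value).strip()).date()


def _sheet_rows(wb, name):
    if name not in wb.sheetnames:
        return []
    rows = list(wb[name].iter_rows(values_only=True))
    if not rows:
        return []
    header = [str(h) if h is not None else "" for h in rows[0]]
    return [dict(zip(header, r)) for r in rows[1:]
            if any(v is not None for v in r)]


def _read_counts(raw_dir: Path) -> dict[tuple[str, str, dt.date], int]:
    counts: dict[tuple[str, str, dt.date], int] = {}
    for path in sorted(Path(raw_dir).iterdir()):
        if "eventslist" not in path.name:
            continue
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (str(row["PatientCode"]), str(row["Monitor"]),
                       _d(row["Date"]))
                n = int(row["RecordedOpenings"]) if "RecordedOpenings" in row else 1
                counts[key] = counts.get(key, 0) + n
    return counts


def oracle_run(aux_path, raw_dir, corrections=True):
    """Recompute per-day and summary implementation from the fixture files.

    Returns a dict with ``monitor_days`` {(patient, monitor, date): 0|1|None},
    ``patient_days`` {(patient, date): 0|1|None}, and ``monitor_rates`` /
    ``patient_rates`` {(key): (monitored, optimal, rate_or_None)}.
    """
    wb = load_workbook(aux_path, read_only=True, data_only=True)
    eminfo = _sheet_rows(wb, "EMInfo")
    regimen = _sheet_rows(wb, "Regimen")
    added = _sheet_rows(wb, "AddedOpenings")
    nmp = _sheet_rows(wb, "NonMonitoredPeriods")
    counts = _read_counts(raw_dir)

    monitor_days: dict[tuple[str, str, dt.date], int | None] = {}
    for em in eminfo:
        p, m = str(em["PatientCode"]), str(em["Monitor"])
        start, end = _d(em["StartDate"]), _d(em["EndDate"])
        day = start
        while day <= end:
            expected = None
            for rg in regimen:
                if (str(rg["PatientCode"]), str(rg["Monitor"])) != (p, m):
                    continue
                rs, re_ = _d(rg["StartDate"]), _d(rg["EndDate"])
                if rs <= day <= re_:
                    e = int(rg["ExpectedOpenings"])
                    if rg.get("On") not in (None, ""):
                        on, off = int(rg["On"]), int(rg["Off"])
                        if (day - rs).days % (on + off) >= on:
                            e = 0
                    expected = e
                    break
            assert expected is not None, f"no regimen covers {day} for {(p, m)}"

            recorded = counts.get((p, m, day), 0)
            corrected = recorded
            censored = False
            if corrections:
                for a in added:
                    if (str(a["PatientCode"]), str(a["Monitor"])) == (p, m) \
                            and _d(a["Date"]) == day:
                        corrected += int(a["Openings"])
                corrected = max(0, corrected)
                for n in nmp:
                    if (str(n["PatientCode"]), str(n["Monitor"])) == (p, m) \
                            and _d(n["StartDate"]) <= day <= _d(n["EndDate"]):
                        censored = True
            monitor_days[(p, m, day)] = None if censored else \
                (1 if corrected >= expected else 0)
            day += dt.timedelta(days=1)

    patient_days: dict[tuple[str, dt.date], int | None] = {}
    for (p, m, day), value in monitor_days.items():
        key = (p, day)
        if key not in patient_days:
            patient_days[key] = value
        else:
            prev = patient_days[key]
            if prev is None or value is None:
                patient_days[key] = None
            else:
                patient_days[key] = prev * value

    def rates(days, key_of):
        out: dict = {}
        for key, value in days.items():
            k = key_of(key)
            mon, opt = out.get(k, (0, 0))
            if value is not None:
                mon += 1
                opt += value
            out[k] = (mon, opt)
        return {k: (mon, opt, opt / mon if mon else None)
                for k, (mon, opt) in out.items()}

    return {
        "monitor_days": monitor_days,
        "patient_days": patient_days,
        "monitor_rates": rates(monitor_days, lambda k: (k[0], k[1])),
        "patient_rates": rates(patient_days, lambda k: k[0]),
    }


def assert_matches_pipeline(oracle, result):
    """Exact agreement between the oracle and a PipelineResult."""
    import pandas as pd

    got_mon = {}
    for _, r in result.ledger.iterrows():
        impl = r["Implementation"]
        got_mon[(r["PatientCode"], r["Monitor"], r["Date"])] = \
            None if pd.isna(impl) else int(impl)
    assert got_mon == oracle["monitor_days"]

    got_pat = {}
    for _, r in result.patient_days.iterrows():
        impl = r["Implementation"]
        got_pat[(r["PatientCode"], r["Date"])] = \
            None if pd.isna(impl) else int(impl)
    assert got_pat == oracle["patient_days"]

    for _, r in result.monitor_summary.iterrows():
        mon, opt, rate = oracle["monitor_rates"][(r["PatientCode"], r["Monitor"])]
        assert (int(r["MonitoredDays"]), int(r["OptimalDays"])) == (mon, opt)
        if rate is None:
            assert pd.isna(r["ImplementationRate"])
        else:
            assert r["ImplementationRate"] == rate
    assert len(result.monitor_summary) == len(oracle["monitor_rates"])

    for _, r in result.patient_summary.iterrows():
        mon, opt, rate = oracle["patient_rates"][r["PatientCode"]]
        assert (int(r["MonitoredDays"]), int(r["OptimalDays"])) == (mon, opt)
        if rate is not None:
            assert r["ImplementationRate"] == rate
    assert len(result.patient_summary) == len(oracle["patient_rates"])
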