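"""Ground-truthed synthetic EM adherence fixtures.

The generator emits exactly the two inputs the pipeline consumes — a
folder of raw ``eventslist`` files and a matching Auxiliary Data workbook
— together with the true per-day implementation, so end-to-end recovery
can be checked exactly.

The simulated cohort mirrors a small oral-anticancer monitoring study:
continuous once-daily regimens, one 21-days-on / 7-days-off cyclic
regimen, one patient alternating two dose strengths between two monitors
(1 day over 2), some patients switching monitors mid-study, and a
mid-study dose change. Per scheduled dose the patient takes it with
probability ``intake_probability``; a taken dose is a *pocket dose* (no
EM opening) with probability ``pocket_dose_rate``; *extra openings*
(curiosity checks) and *nonmonitored periods* (EM nonuse) are injected
at their configured rates. Every injected deviation perturbs the raw
events AND appears as the corresponding auxiliary row
(``AddedOpenings`` / ``NonMonitoredPeriods``), so full cleaning recovers
the truth exactly; deviations are never placed on censored days, keeping
the truth unambiguous.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aux_schema import (AdverseEventRecord, AuxiliaryData, MonitorWindow,
                         NonMonitoredPeriod, OpeningAdjustment, RegimenPeriod,
                         write_auxiliary)
from .dates import date_range

_DRUGS = ["pazopanib", "trametinib", "dabrafenib", "everolimus",
          "alectinib", "erlotinib"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a 10-patient cohort with 15 monitors (5 patients
    use 2 EMs), monitor-use periods lognormal around a median of 187
    days, near-perfect intake (p = 0.97) and modest EM-use deviations —
    a cohort in which raw (uncleaned) implementation understates true
    adherence by roughly 10-15 percentage points.
    """

    n_patients: int = 10
    two_monitor_patients: int = 5
    include_cyclic: bool = True          # one palbociclib-style 21/7 monitor
    include_alternating: bool = True     # one imatinib-style alternating EM pair
    include_regimen_change: bool = True  # one mid-study dose change
    expected_openings: int = 1
    intake_probability: float = 0.97     # per scheduled dose
    pocket_dose_rate: float = 0.07       # per taken dose
    extra_opening_rate: float = 0.01     # per monitored day
    nonmonitored_rate: float = 0.01      # per day: chance an EM-nonuse interval starts
    nonmonitored_length: tuple[int, int] = (4, 10)   # interval length range, days
    window_days_median: float = 187.0
    window_days_sigma: float = 0.6       # lognormal sigma; 0 = fixed length
    window_days_min: int = 60
    window_days_max: int = 450
    start_date: dt.date = dt.date(2021, 1, 4)
    raw_format: str = "events"           # "events" | "daily"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.two_monitor_patients <= self.n_patients:
            raise ValueError("two_monitor_patients must be in [0, n_patients]")
        for name in ("intake_probability", "pocket_dose_rate",
                     "extra_opening_rate", "nonmonitored_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.expected_openings < 1:
            raise ValueError("expected_openings must be >= 1")
        if self.window_days_min < 2 or self.window_days_min > self.window_days_max:
            raise ValueError("window day bounds must satisfy 2 <= min <= max")
        a, b = self.nonmonitored_length
        if not 1 <= a <= b:
            raise ValueError("nonmonitored_length must satisfy 1 <= min <= max")
        if self.raw_format not in ("events", "daily"):
            raise ValueError("raw_format must be 'events' or 'daily'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "start_date" in data and isinstance(data["start_date"], str):
            data["start_date"] = dt.date.fromisoformat(data["start_date"])
        if "nonmonitored_length" in data:
            data["nonmonitored_length"] = tuple(data["nonmonitored_length"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class _MonitorPlan:
    patient: str
    monitor: str
    start: dt.date
    end: dt.date
    periods: list[RegimenPeriod]
    drug: str
    regimen_type: str

    def expected(self, d: dt.date) -> int:
        for p in self.periods:
            if p.start_date <= d <= p.end_date:
                if p.on_days is None:
                    return p.expected_openings
                k = (d - p.start_date).days % (p.on_days + p.off_days)
                return p.expected_openings if k < p.on_days else 0
        raise AssertionError(f"{d} uncovered in plan for {self.monitor}")


@dataclass
class SimulationResult:
    """Fixture paths plus the generator's ground truth."""

    out_dir: Path
    raw_folder: Path
    aux_path: Path
    truth_by_monitor: pd.DataFrame
    truth_by_patient: pd.DataFrame
    truth_monitor_summary: pd.DataFrame
    truth_patient_summary: pd.DataFrame
    config: SimulationConfig


def _draw_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    if cfg.window_days_sigma == 0:
        length = cfg.window_days_median
    else:
        length = rng.lognormal(math.log(cfg.window_days_median),
                               cfg.window_days_sigma)
    return int(min(max(round(length), cfg.window_days_min), cfg.window_days_max))


def _plan_monitors(rng: np.random.Generator,
                   cfg: SimulationConfig) -> list[_MonitorPlan]:
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    two_em = patients[cfg.n_patients - cfg.two_monitor_patients:] \
        if cfg.two_monitor_patients else []
    singles = [p for p in patients if p not in two_em]
    cyclic_patient = singles[0] if cfg.include_cyclic and singles else None
    change_patient = singles[1] if cfg.include_regimen_change and len(singles) > 1 else None
    alternating_patient = two_em[0] if cfg.include_alternating and two_em else None

    plans: list[_MonitorPlan] = []
    counter = 0
    drug_i = 0

    def next_monitor() -> str:
        nonlocal counter
        counter += 1
        return f"M{counter:02d}"

    def next_drug() -> str:
        nonlocal drug_i
        drug = _DRUGS[drug_i % len(_DRUGS)]
        drug_i += 1
        return drug

    for patient in patients:
        start = cfg.start_date + dt.timedelta(days=int(rng.integers(0, 61)))
        if patient in two_em and patient == alternating_patient:
            # two dose strengths alternated day over day between two EMs
            length = _draw_length(rng, cfg)
            m1, m2 = next_monitor(), next_monitor()
            end = start + dt.timedelta(days=length - 1)
            s2 = min(start + dt.timedelta(days=1), end)
            plans.append(_MonitorPlan(
                patient, m1, start, end,
                [RegimenPeriod(patient, m1, cfg.expected_openings, start, end, 1, 1)],
                "imatinib", "cyclic"))
            plans.append(_MonitorPlan(
                patient, m2, s2, end,
                [RegimenPeriod(patient, m2, cfg.expected_openings, s2, end, 1, 1)],
                "imatinib", "cyclic"))
        elif patient in two_em:
            # monitor switched mid-study: two consecutive use periods
            drug = next_drug()
            for _ in range(2):
                length = _draw_length(rng, cfg)
                m = next_monitor()
                end = start + dt.timedelta(days=length - 1)
                plans.append(_MonitorPlan(
                    patient, m, start, end,
                    [RegimenPeriod(patient, m, cfg.expected_openings, start, end)],
                    drug, "continuous"))
                start = end + dt.timedelta(days=1)
        elif patient == cyclic_patient:
            length = _draw_length(rng, cfg)
            m = next_monitor()
            end = start + dt.timedelta(days=length - 1)
            plans.append(_MonitorPlan(
                patient, m, start, end,
                [RegimenPeriod(patient, m, cfg.expected_openings, start, end, 21, 7)],
                "palbociclib", "cyclic"))
        elif patient == change_patient:
            length = max(_draw_length(rng, cfg), 2)
            m = next_monitor()
            end = start + dt.timedelta(days=length - 1)
            mid = start + dt.timedelta(days=length // 2)
            plans.append(_MonitorPlan(
                patient, m, start, end,
                [RegimenPeriod(patient, m, cfg.expected_openings, start,
                               mid - dt.timedelta(days=1)),
                 RegimenPeriod(patient, m, cfg.expected_openings + 1, mid, end)],
                next_drug(), "continuous"))
        else:
            length = _draw_length(rng, cfg)
            m = next_monitor()
            end = start + dt.timedelta(days=length - 1)
            plans.append(_MonitorPlan(
                patient, m, start, end,
                [RegimenPeriod(patient, m, cfg.expected_openings, start, end)],
                next_drug(), "continuous"))
    return plans


def _censoring_intervals(rng: np.random.Generator, cfg: SimulationConfig,
                         n_days: int) -> list[tuple[int, int]]:
    """Merged day-index intervals of EM nonuse."""
    lo, hi = cfg.nonmonitored_length
    raw: list[tuple[int, int]] = []
    starts = rng.random(n_days) < cfg.nonmonitored_rate
    for i in np.flatnonzero(starts):
        length = int(rng.integers(lo, hi + 1))
        raw.append((int(i), min(int(i) + length - 1, n_days - 1)))
    raw.sort()
    merged: list[tuple[int, int]] = []
    for a, b in raw:
        if merged and a <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def simulate(config: SimulationConfig, out_dir: str | Path) -> SimulationResult:
    """Generate a fixture tree under ``out_dir``.

    Layout: ``raw/`` with per-patient ``*_eventslist*`` files,
    ``auxiliary.xlsx``, and four ``truth_*.csv`` tables (per monitor-day,
    per patient-day, and the two summaries). Fixed seed implies
    byte-identical outputs.
    """
    config.validate()
    out_dir = Path(out_dir)
    raw_dir = out_dir / "raw"
    raw_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    plans = _plan_monitors(rng, config)
    aux = AuxiliaryData()
    events: dict[str, list[tuple[str, str, dt.datetime]]] = {}
    truth_rows = []

    for plan in plans:
        aux.windows.append(MonitorWindow(plan.patient, plan.monitor,
                                         plan.start, plan.end))
        aux.regimens.extend(plan.periods)
        days = date_range(plan.start, plan.end)
        censored: set[int] = set()
        for a, b in _censoring_intervals(rng, config, len(days)):
            censored.update(range(a, b + 1))
            aux.nonmonitored.append(NonMonitoredPeriod(
                plan.patient, plan.monitor, days[a], days[b]))
        ev = events.setdefault(plan.patient, [])
        for idx, day in enumerate(days):
            e = plan.expected(day)
            if idx in censored:
                truth_rows.append((plan.patient, plan.monitor, day, e, 0, None))
                continue
            intakes = int(rng.binomial(e, config.intake_probability)) if e else 0
            pockets = int(rng.binomial(intakes, config.pocket_dose_rate)) \
                if intakes else 0
            openings = intakes - pockets
            for _ in range(openings):
                clock = 7 * 3600 + int(rng.integers(0, 15 * 3600))
                ev.append((plan.patient, plan.monitor,
                           dt.datetime.combine(day, dt.time(0)) +
                           dt.timedelta(seconds=clock)))
            if pockets:
                aux.adjustments.append(OpeningAdjustment(
                    plan.patient, plan.monitor, day, pockets))
            if rng.random() < config.extra_opening_rate:
                clock = 7 * 3600 + int(rng.integers(0, 15 * 3600))
                ev.append((plan.patient, plan.monitor,
                           dt.datetime.combine(day, dt.time(0)) +
                           dt.timedelta(seconds=clock)))
                aux.adjustments.append(OpeningAdjustment(
                    plan.patient, plan.monitor, day, -1))
            truth_rows.append((plan.patient, plan.monitor, day, e, intakes,
                               1 if intakes >= e else 0))

    # enrichment sheets
    patients = sorted({p.patient for p in plans})
    aux.patient_covariables = pd.DataFrame({
        "PatientCode": patients,
        "Age": [int(rng.integers(40, 76)) for _ in patients],
        "Gender": [("F" if rng.random() < 0.5 else "M") for _ in patients],
    })
    aux.monitor_covariables = pd.DataFrame(
        [(p.patient, p.monitor, p.drug, p.regimen_type) for p in plans],
        columns=["PatientCode", "Monitor", "Drug", "RegimenType"])
    for patient in patients:
        if rng.random() < 0.5:
            windows = [p for p in plans if p.patient == patient]
            w = windows[0]
            offset = int(rng.integers(0, (w.end - w.start).days + 1))
            aux.adverse_events.append(AdverseEventRecord(
                patient, w.start + dt.timedelta(days=offset), "Fatigue", "1"))

    aux_path = out_dir / "auxiliary.xlsx"
    write_auxiliary(aux, aux_path)
    _write_raw(events, raw_dir, config.raw_format)

    truth_mon = pd.DataFrame(
        truth_rows, columns=["PatientCode", "Monitor", "Date", "Expected",
                             "Intakes", "Implementation"])
    truth_mon["Implementation"] = truth_mon["Implementation"].astype("Int64")
    truth_mon = truth_mon.sort_values(
        ["PatientCode", "Monitor", "Date"]).reset_index(drop=True)
    truth_pat = _truth_patient_days(truth_mon)
    truth_msum = _truth_summary(truth_mon, ["PatientCode", "Monitor"])
    truth_psum = _truth_summary(truth_pat, ["PatientCode"])

    truth_mon.to_csv(out_dir / "truth_by_monitor.csv", index=False)
    truth_pat.to_csv(out_dir / "truth_by_patient.csv", index=False)
    truth_msum.to_csv(out_dir / "truth_summary_by_monitor.csv", index=False)
    truth_psum.to_csv(out_dir / "truth_summary_by_patient.csv", index=False)

    return SimulationResult(out_dir, raw_dir, aux_path, truth_mon, truth_pat,
                            truth_msum, truth_psum, config)


def _write_raw(events: dict[str, list[tuple[str, str, dt.datetime]]],
               raw_dir: Path, raw_format: str) -> None:
    for patient in sorted(events):
        rows = sorted(events[patient], key=lambda r: (r[1], r[2]))
        if raw_format == "events":
            path = raw_dir / f"{patient}_eventslist.csv"
            lines = ["PatientCode,Monitor,Date"]
            lines += [f"{p},{m},{ts:%Y-%m-%d %H:%M:%S}" for p, m, ts in rows]
        else:
            path = raw_dir / f"{patient}_eventslist_daily.csv"
            counts: dict[tuple[str, dt.date], int] = {}
            for p, m, ts in rows:
                counts[(m, ts.date())] = counts.get((m, ts.date()), 0) + 1
            lines = ["PatientCode,Monitor,Date,RecordedOpenings"]
            lines += [f"{patient},{m},{d:%Y-%m-%d},{n}"
                      for (m, d), n in sorted(counts.items())]
        path.write_text("\n".join(lines) + "\n")


def _truth_patient_days(truth_mon: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (patient, day), grp in truth_mon.groupby(["PatientCode", "Date"], sort=True):
        vals = grp["Implementation"]
        impl = pd.NA if vals.isna().any() else int(vals.min())
        rows.append((patient, day, len(grp), impl))
    df = pd.DataFrame(rows, columns=["PatientCode", "Date", "MonitorsInScope",
                                     "Implementation"])
    df["Implementation"] = df["Implementation"].astype("Int64")
    return df


def _truth_summary(days: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    rows = []
    for key, grp in days.groupby(keys, sort=True):
        vals = grp["Implementation"]
        monitored = int(vals.notna().sum())
        optimal = int((vals == 1).sum())
        rate = optimal / monitored if monitored else None
        rows.append((*key, monitored, optimal, rate))
    return pd.DataFrame(rows, columns=keys + ["MonitoredDays", "OptimalDays",
                                              "ImplementationRate"])


def small_config(rng: np.random.Generator, **overrides) -> SimulationConfig:
    """Randomised miniature study conditions for property testing.

    Draws a cohort of at most 5 patients with short windows and moderate
    deviation rates; ``overrides`` pin any field.
    """
    n = int(rng.integers(1, 6))
    cfg = SimulationConfig(
        n_patients=n,
        two_monitor_patients=int(rng.integers(0, min(n, 2) + 1)),
        include_cyclic=bool(rng.random() < 0.7),
        include_alternating=bool(rng.random() < 0.7),
        include_regimen_change=bool(rng.random() < 0.5),
        expected_openings=int(rng.integers(1, 3)),
        intake_probability=float(rng.uniform(0.5, 1.0)),
        pocket_dose_rate=float(rng.uniform(0.0, 0.15)),
        extra_opening_rate=float(rng.uniform(0.0, 0.05)),
        nonmonitored_rate=float(rng.uniform(0.0, 0.04)),
        nonmonitored_length=(2, 6),
        window_days_median=35.0,
        window_days_sigma=0.25,
        window_days_min=12,
        window_days_max=58,
        raw_format="events" if rng.random() < 0.7 else "daily",
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg
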