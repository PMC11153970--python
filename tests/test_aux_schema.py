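"""Auxiliary workbook parsing, validation and round-trip behaviour."""

import datetime as dt

import numpy as np
import pytest

from adhclean import validation as V
from adhclean.aux_schema import (load_auxiliary, validate_cross_references,
                                 write_auxiliary)
from adhclean.synthetic_data import SimulationConfig, simulate

from conftest import D, make_workbook


def codes(findings):
    return [f.code for f in findings]


class TestLoadAuxiliary:
    def test_minimal_workbook_is_clean(self, tmp_path, minimal_sheets):
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        aux, report = load_auxiliary(path)
        assert report.errors == [] and report.warnings == []
        assert len(aux.windows) == 1 and len(aux.regimens) == 1
        assert aux.adjustments == [] and aux.nonmonitored == []
        assert aux.adverse_events == []
        assert aux.patient_covariables is None

        w = aux.windows[0]
        assert w.key == ("P01", "M1")
        assert (w.start_date, w.end_date) == (D(2021, 5, 1), D(2021, 5, 10))
        assert w.length_days == 10

    def test_on_without_off_is_critical(self, tmp_path, minimal_sheets):
        minimal_sheets["Regimen"].append(
            ["P01", "M1", 1, D(2021, 5, 11), D(2021, 6, 10), 21, None])
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        aux, report = load_auxiliary(path)
        assert codes(report.errors) == [V.ON_OFF_PAIR]
        assert report.errors[0].row == 3
        assert len(aux.regimens) == 1  # bad row excluded

    def test_text_garbage_date_is_critical_with_location(self, tmp_path,
                                                         minimal_sheets):
        minimal_sheets["EMInfo"].append(["P02", "M2", "notadate", D(2021, 6, 1)])
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        _, report = load_auxiliary(path)
        assert codes(report.errors) == [V.BAD_DATE]
        assert report.errors[0].location == "EMInfo"
        assert report.errors[0].row == 3

    def test_ambiguous_slash_date_rejected_not_guessed(self, tmp_path,
                                                       minimal_sheets):
        minimal_sheets["EMInfo"][1][2] = "03/04/2021"
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        _, report = load_auxiliary(path)
        assert V.BAD_DATE in codes(report.errors)

    def test_missing_mandatory_sheet(self, tmp_path, minimal_sheets):
        del minimal_sheets["Regimen"]
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        _, report = load_auxiliary(path)
        assert codes(report.errors) == [V.MISSING_SHEET]

    def test_missing_mandatory_column(self, tmp_path, minimal_sheets):
        minimal_sheets["EMInfo"] = [["PatientCode", "Monitor", "StartDate"],
                                    ["P01", "M1", D(2021, 5, 1)]]
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        _, report = load_auxiliary(path)
        assert V.MISSING_COLUMN in codes(report.errors)

    def test_column_names_case_sensitive(self, tmp_path, minimal_sheets):
        minimal_sheets["EMInfo"][0] = ["patientcode", "Monitor", "StartDate",
                                       "EndDate"]
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        _, report = load_auxiliary(path)
        assert V.MISSING_COLUMN in codes(report.errors)

    def test_extra_columns_ignored(self, tmp_path, minimal_sheets):
        minimal_sheets["EMInfo"][0].append("Comments")
        minimal_sheets["EMInfo"][1].append("free text")
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        aux, report = load_auxiliary(path)
        assert report.ok and len(aux.windows) == 1

    def test_start_after_end_is_critical(self, tmp_path, minimal_sheets):
        minimal_sheets["EMInfo"].append(["P02", "M2", D(2021, 6, 10),
                                         D(2021, 6, 1)])
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        _, report = load_auxiliary(path)
        assert codes(report.errors) == [V.DATE_ORDER]

    def test_zero_delta_adjustment_warns_and_drops(self, tmp_path, minimal_sheets):
        minimal_sheets["AddedOpenings"] = [
            ["PatientCode", "Monitor", "Date", "Openings"],
            ["P01", "M1", D(2021, 5, 3), 0],
            ["P01", "M1", D(2021, 5, 4), 2],
        ]
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        aux, report = load_auxiliary(path)
        assert codes(report.warnings) == [V.ZERO_DELTA]
        assert [a.openings_delta for a in aux.adjustments] == [2]

    def test_error_monotonicity_under_added_malformed_rows(self, tmp_path,
                                                           minimal_sheets):
        base = make_workbook(tmp_path / "a.xlsx", minimal_sheets)
        _, before = load_auxiliary(base)
        minimal_sheets["EMInfo"].append(["P09", "M9", "junk", "junk"])
        minimal_sheets["Regimen"].append(["P09", "M9", -1, D(2021, 1, 1),
                                          D(2021, 1, 2), None, None])
        worse = make_workbook(tmp_path / "b.xlsx", minimal_sheets)
        _, after = load_auxiliary(worse)
        assert set(before.errors) <= set(after.errors)
        assert set(before.warnings) <= set(after.warnings)


class TestCrossReferences:
    def test_declared_monitor_without_raw_data_warns(self, tmp_path,
                                                     minimal_sheets):
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        aux, _ = load_auxiliary(path)
        report = validate_cross_references(aux, monitors_seen_in_raw=set())
        assert codes(report.errors) == []
        assert codes(report.warnings) == [V.NO_RAW_DATA]

    def test_undeclared_monitor_in_raw_warns(self, tmp_path, minimal_sheets):
        path = make_workbook(tmp_path / "aux.xlsx", minimal_sheets)
        aux, _ = load_auxiliary(path)
        report = validate_cross_references(aux, {("P01", "M1"), ("P99", "MX")})
        assert codes(report.warnings) == [V.UNDECLARED_MONITOR]

    def test_overlapping_regimen_periods_are_critical(self, tmp_path):
        sheets = {
            "EMInfo": [["PatientCode", "Monitor", "StartDate", "EndDate"],
                       ["P01", "M1", D(2021, 1, 1), D(2021, 2, 10)]],
            "Regimen": [
                ["PatientCode", "Monitor", "ExpectedOpenings", "StartDate",
                 "EndDate"],
                ["P01", "M1", 1, D(2021, 1, 1), D(2021, 1, 31)],
                ["P01", "M1", 2, D(2021, 1, 15), D(2021, 2, 10)],
            ],
        }
        aux, _ = load_auxiliary(make_workbook(tmp_path / "aux.xlsx", sheets))
        report = validate_cross_references(aux, {("P01", "M1")})
        assert V.REGIMEN_OVERLAP in codes(report.errors)

    def test_regimen_gap_inside_window_is_critical(self, tmp_path):
        sheets = {
            "EMInfo": [["PatientCode", "Monitor", "StartDate", "EndDate"],
                       ["P01", "M1", D(2021, 1, 1), D(2021, 1, 31)]],
            "Regimen": [
                ["PatientCode", "Monitor", "ExpectedOpenings", "StartDate",
                 "EndDate"],
                ["P01", "M1", 1, D(2021, 1, 1), D(2021, 1, 10)],
                ["P01", "M1", 1, D(2021, 1, 21), D(2021, 1, 31)],
            ],
        }
        aux, _ = load_auxiliary(make_workbook(tmp_path / "aux.xlsx", sheets))
        report = validate_cross_references(aux, {("P01", "M1")})
        gaps = [e for e in report.errors if e.code == V.REGIMEN_GAP]
        assert len(gaps) == 1 and "2021-01-11..2021-01-20" in gaps[0].message

    def test_orphan_auxiliary_rows_are_critical(self, tmp_path, minimal_sheets):
        minimal_sheets["NonMonitoredPeriods"] = [
            ["PatientCode", "Monitor", "StartDate", "EndDate"],
            ["P77", "M77", D(2021, 5, 2), D(2021, 5, 3)],
        ]
        minimal_sheets["AddedOpenings"] = [
            ["PatientCode", "Monitor", "Date", "Openings"],
            ["P88", "M88", D(2021, 5, 2), 1],
        ]
        aux, _ = load_auxiliary(make_workbook(tmp_path / "aux.xlsx",
                                              minimal_sheets))
        report = validate_cross_references(aux, {("P01", "M1")})
        assert codes(report.errors).count(V.ORPHAN_ROW) == 2


class TestRoundTrip:
    def test_write_then_load_preserves_all_records(self, tmp_path):
        rng = np.random.default_rng(7)
        cfg = SimulationConfig(n_patients=3, two_monitor_patients=2,
                               window_days_median=30, window_days_sigma=0.2,
                               window_days_min=10, window_days_max=45,
                               pocket_dose_rate=0.2, nonmonitored_rate=0.05,
                               nonmonitored_length=(2, 4), seed=int(rng.integers(1e6)))
        res = simulate(cfg, tmp_path / "sim")
        aux, report = load_auxiliary(res.aux_path)
        assert report.ok
        assert aux.adjustments and aux.nonmonitored  # fixture non-trivial

        copy = tmp_path / "copy.xlsx"
        write_auxiliary(aux, copy)
        aux2, report2 = load_auxiliary(copy)
        assert report2.ok
        assert aux2.windows == aux.windows
        assert aux2.regimens == aux.regimens
        assert aux2.adjustments == aux.adjustments
        assert aux2.nonmonitored == aux.nonmonitored
        assert aux2.adverse_events == aux.adverse_events
        assert aux2.patient_covariables.astype(str).equals(
            aux.patient_covariables.astype(str))
        assert aux2.monitor_covariables.astype(str).equals(
            aux.monitor_covariables.astype(str))
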