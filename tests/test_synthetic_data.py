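"""Generator: ground truth, recovery, determinism, degenerate configs."""

import filecmp
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from adhclean.pipeline import run_pipeline
from adhclean.synthetic_data import SimulationConfig, simulate, small_config


def tree_bytes(root: Path) -> dict[str, bytes]:
    return {str(p.relative_to(root)): p.read_bytes()
            for p in sorted(root.rglob("*")) if p.is_file()}


def assert_recovers_truth(res, out):
    merged = out.ledger[["PatientCode", "Monitor", "Date", "Implementation"]] \
        .merge(res.truth_by_monitor, on=["PatientCode", "Monitor", "Date"],
               how="outer", suffixes=("_got", "_want"))
    assert len(merged) == len(res.truth_by_monitor) == len(out.ledger)
    got, want = merged["Implementation_got"], merged["Implementation_want"]
    assert ((got.isna() & want.isna()) | (got == want)).all()

    psum = out.patient_summary[["PatientCode", "MonitoredDays", "OptimalDays",
                                "ImplementationRate"]]
    truth = res.truth_patient_summary
    assert psum.reset_index(drop=True).equals(truth[psum.columns])


class TestRecovery:
    def test_perfect_adherence_rate_one(self, tmp_path):
        cfg = SimulationConfig(n_patients=2, two_monitor_patients=0,
                               include_cyclic=False, include_regimen_change=False,
                               intake_probability=1.0, pocket_dose_rate=0.0,
                               extra_opening_rate=0.0, nonmonitored_rate=0.0,
                               window_days_median=30, window_days_sigma=0.0,
                               window_days_min=30, window_days_max=30, seed=1)
        res = simulate(cfg, tmp_path)
        assert (res.truth_patient_summary["ImplementationRate"] == 1.0).all()
        out = run_pipeline(res.aux_path, res.raw_folder)
        assert out.ok
        assert (out.patient_summary["ImplementationRate"] == 1.0).all()

    def test_pocket_doses_cleaned_rate_exceeds_raw_and_equals_truth(self,
                                                                    tmp_path):
        cfg = SimulationConfig(n_patients=3, two_monitor_patients=0,
                               include_cyclic=False, include_regimen_change=False,
                               intake_probability=0.9, pocket_dose_rate=0.3,
                               extra_opening_rate=0.0, nonmonitored_rate=0.0,
                               window_days_median=40, window_days_sigma=0.0,
                               window_days_min=40, window_days_max=40, seed=5)
        res = simulate(cfg, tmp_path)
        assert res.out_dir.joinpath("auxiliary.xlsx").exists()
        clean = run_pipeline(res.aux_path, res.raw_folder)
        raw = run_pipeline(res.aux_path, res.raw_folder, corrections=False)
        assert_recovers_truth(res, clean)
        assert (clean.patient_summary["ImplementationRate"].mean() >
                raw.patient_summary["ImplementationRate"].mean())

    def test_miniature_default_cohort_runs_clean(self, tmp_path):
        """10 patients / 15 monitors with a 21/7 cycle and an alternating EM
        pair, shortened windows: the full pipeline runs with 0 errors."""
        cfg = replace(SimulationConfig(), window_days_median=60,
                      window_days_sigma=0.3, window_days_min=30,
                      window_days_max=90, seed=42)
        res = simulate(cfg, tmp_path)
        out = run_pipeline(res.aux_path, res.raw_folder,
                           out=tmp_path / "impl.xlsx")
        assert out.report.errors == []
        assert len(out.monitor_summary) == 15
        assert len(out.patient_summary) == 10
        assert_recovers_truth(res, out)

    def test_daily_adherence_format_recovers_identically(self, tmp_path):
        cfg = SimulationConfig(n_patients=2, two_monitor_patients=1,
                               window_days_median=25, window_days_sigma=0.1,
                               window_days_min=12, window_days_max=40,
                               raw_format="daily", seed=9)
        res = simulate(cfg, tmp_path)
        out = run_pipeline(res.aux_path, res.raw_folder)
        assert out.ok
        assert_recovers_truth(res, out)


class TestDeterminismAndConfig:
    def test_same_seed_byte_identical_tree(self, tmp_path):
        cfg = SimulationConfig(n_patients=3, two_monitor_patients=1,
                               window_days_median=25, window_days_sigma=0.2,
                               window_days_min=10, window_days_max=40, seed=17)
        a = simulate(cfg, tmp_path / "a")
        b = simulate(cfg, tmp_path / "b")
        assert tree_bytes(a.out_dir) == tree_bytes(b.out_dir)

    def test_different_seed_differs(self, tmp_path):
        cfg = SimulationConfig(n_patients=3, window_days_median=25,
                               window_days_sigma=0.2, window_days_min=10,
                               window_days_max=40, two_monitor_patients=1,
                               seed=17)
        a = simulate(cfg, tmp_path / "a")
        b = simulate(replace(cfg, seed=18), tmp_path / "b")
        assert tree_bytes(a.out_dir) != tree_bytes(b.out_dir)

    @pytest.mark.parametrize("bad", [
        {"n_patients": 0},
        {"intake_probability": 1.5},
        {"window_days_min": 0},
        {"two_monitor_patients": 99},
        {"raw_format": "parquet"},
    ])
    def test_degenerate_config_rejected(self, tmp_path, bad):
        cfg = replace(SimulationConfig(), **bad)
        with pytest.raises(ValueError):
            simulate(cfg, tmp_path)

    def test_raw_vs_clean_gap_monotone_in_deviation_rates(self, tmp_path):
        """More injected pocket doses / EM-nonuse widen the raw-vs-clean gap."""
        gaps = []
        for i, (pocket, nmp) in enumerate([(0.0, 0.0), (0.1, 0.01),
                                           (0.3, 0.03)]):
            cfg = SimulationConfig(n_patients=4, two_monitor_patients=0,
                                   include_cyclic=False,
                                   include_regimen_change=False,
                                   intake_probability=0.95,
                                   pocket_dose_rate=pocket,
                                   extra_opening_rate=0.0,
                                   nonmonitored_rate=nmp,
                                   window_days_median=80, window_days_sigma=0.0,
                                   window_days_min=80, window_days_max=80,
                                   seed=23)
            res = simulate(cfg, tmp_path / str(i))
            clean = run_pipeline(res.aux_path, res.raw_folder)
            raw = run_pipeline(res.aux_path, res.raw_folder, corrections=False)
            gaps.append(clean.patient_summary["ImplementationRate"].mean() -
                        raw.patient_summary["ImplementationRate"].mean())
        assert gaps[0] == 0.0
        assert gaps[0] <= gaps[1] <= gaps[2]


class TestSmallConfig:
    def test_small_config_draws_valid_miniatures(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            cfg = small_config(rng)
            assert 1 <= cfg.n_patients <= 5
            assert cfg.window_days_max <= 58
            cfg.validate()
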