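import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from delaystand.interface.cli import main
from delaystand.interface.replicate import replicate
from delaystand.interface.runlog import RunManifest, log_context
from delaystand.interface.trialio import SchemaError, TrialRecord, read_trial, write_trial


def small_trial(n=500, fs=100.0):
    t = np.arange(n) / fs
    return TrialRecord(
        fs=fs, time_s=t, theta_deg=np.sin(t), theta_dot_dps=np.cos(t),
        torque_nm=0.1 * t, delay_ms=np.full(n, 20.0),
        evs_ma=np.zeros(n), emg_au=np.ones(n), button=np.zeros(n, dtype=np.int8),
        meta={"experiment": "test", "periods": [[1.0, 200.0, 2.0]]},
    )


class TestTrialIO:
    def test_round_trip_identical(self, tmp_path):
        tr = small_trial()
        path = write_trial(tr, tmp_path / "t.csv")
        back = read_trial(path)
        assert back.fs == tr.fs
        for name in ("time_s", "theta_deg", "theta_dot_dps", "torque_nm",
                     "delay_ms", "evs_ma", "emg_au", "button"):
            np.testing.assert_allclose(getattr(back, name), getattr(tr, name),
                                       atol=1e-12)
        assert back.meta["experiment"] == "test"

    def test_missing_delay_column_named(self, tmp_path):
        tr = small_trial()
        path = write_trial(tr, tmp_path / "t.csv")
        df = pd.read_csv(path)
        df.drop(columns=["time_s"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="time_s"):
            read_trial(path)

    def test_fs_mismatch_rejected(self, tmp_path):
        tr = small_trial()
        path = write_trial(tr, tmp_path / "t.csv")
        sidecar = path.with_suffix(".csv.json")
        meta = json.loads(sidecar.read_text())
        meta["fs"] = 250.0
        sidecar.write_text(json.dumps(meta))
        with pytest.raises(SchemaError, match="fs"):
            read_trial(path)

    def test_missing_sidecar_rejected(self, tmp_path):
        tr = small_trial()
        path = write_trial(tr, tmp_path / "t.csv")
        path.with_suffix(".csv.json").unlink()
        with pytest.raises(SchemaError, match="sidecar"):
            read_trial(path)

    def test_non_monotone_time_rejected(self):
        with pytest.raises(SchemaError, match="time_s"):
            TrialRecord(fs=100.0, time_s=np.array([0.0, 0.2, 0.1]))

    def test_length_mismatch_names_column(self):
        with pytest.raises(SchemaError, match="theta_deg"):
            TrialRecord(fs=100.0, time_s=np.arange(5) / 100.0,
                        theta_deg=np.zeros(4))

    def test_60s_at_2000hz_has_120000_rows(self, tmp_path):
        n = 120000
        tr = TrialRecord(fs=2000.0, time_s=np.arange(n) / 2000.0)
        path = write_trial(tr, tmp_path / "big.csv")
        assert len(read_trial(path)) == 120000


class TestRunlog:
    def test_log_context_returns_record(self):
        rec = log_context("vest", L=76, nfft=2048)
        assert rec == {"stage": "vest", "L": 76, "nfft": 2048}

    def test_manifest_digest_stable(self, tmp_path):
        m1 = RunManifest(experiment="exp1", seed=3, configs={"a": 1})
        m2 = RunManifest(experiment="exp1", seed=3, configs={"a": 1})
        assert m1.digest() == m2.digest()
        m3 = RunManifest(experiment="exp1", seed=4, configs={"a": 1})
        assert m1.digest() != m3.digest()


class TestReplicate:
    def test_exp2_percept_bundle(self, tmp_path):
        manifest = replicate("exp2-percept", seed=1, out_dir=tmp_path / "p")
        table = pd.read_csv(tmp_path / "p" / "exp2_percept_table.csv")
        assert len(table) == 7
        assert (table["presented"] == table["used"] + table["excluded"]).all()
        summary = json.loads((tmp_path / "p" / "exp2_percept_summary.json").read_text())
        assert 50.0 < summary["threshold70_ms"] < 350.0

    def test_exp2_percept_deterministic_digests(self, tmp_path):
        m1 = replicate("exp2-percept", seed=2, out_dir=tmp_path / "a")
        m2 = replicate("exp2-percept", seed=2, out_dir=tmp_path / "b")
        assert list(m1.outputs.values()) == list(m2.outputs.values())

    def test_training_bundle_reports_decreasing_exponential(self, tmp_path):
        replicate("training", seed=2, out_dir=tmp_path / "tr")
        bundle = json.loads((tmp_path / "tr" / "training_learning_curve.json").read_text())
        fit = bundle["variance_fit"]
        assert set(fit) == {"a", "b", "c", "value_at_tc"}
        assert fit["a"] > 0 and fit["b"] > 0  # variance decays with training
        assert fit["value_at_tc"] == pytest.approx(
            fit["a"] * np.exp(-1) + fit["c"], abs=1e-9)
        assert len(bundle["minutes"]) == 100

    def test_exp3_bundle_landmarks(self, tmp_path):
        replicate("exp3", seed=1, out_dir=tmp_path / "e3")
        bundle = json.loads((tmp_path / "e3" / "exp3_transition_maps.json").read_text())
        assert bundle["tc_95_s"] == pytest.approx(3 * bundle["tc_63_s"])
        assert bundle["gain_tc_63_s"] == pytest.approx(bundle["injected_tau_s"],
                                                       rel=0.5)

    def test_exp2_vest_coupling_attenuates_with_delay(self, tmp_path):
        replicate("exp2-vest", seed=1, out_dir=tmp_path / "ev")
        df = pd.read_csv(tmp_path / "ev" / "exp2_vest_coupling.csv")
        pp = df.sort_values("delay_ms")["cross_cov_peak_to_peak"].to_numpy()
        assert all(a > b for a, b in zip(pp, pp[1:]))
        assert (df["L"] == 78).all()

    def test_unknown_tag_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown experiment"):
            replicate("nope", seed=0, out_dir=tmp_path)

    def test_exp1_bundle_six_conditions(self, tmp_path):
        replicate("exp1", seed=0, out_dir=tmp_path / "e1")
        df = pd.read_csv(tmp_path / "e1" / "exp1_delay_table.csv")
        assert sorted(df["delay_ms"]) == [20, 100, 200, 300, 400, 500]
        assert {"sway_velocity_variance", "percent_within_limits"} <= set(df.columns)


class TestCli:
    def test_simulate_and_sway_report(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.txt"
        cfg.write_text("mass_kg = 75\nsample_rate_hz = 200\n")
        out = tmp_path / "trial.csv"
        r = runner.invoke(main, ["simulate", "--config", str(cfg),
                                 "--delay-ms", "20", "--duration-s", "10",
                                 "--seed", "1", "--out", str(out)])
        assert r.exit_code == 0, r.output
        report = tmp_path / "report.csv"
        r = runner.invoke(main, ["sway", "--in", str(out),
                                 "--report", str(report)])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(report)
        assert "sway_velocity_variance" in df.columns

    def test_synth_writes_trials(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "synth"
        r = runner.invoke(main, ["synth", "--experiment", "exp1", "--seed", "0",
                                 "--fs", "200", "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert len(list(out.glob("*.csv"))) == 6
        assert (out / "ground_truth.json").exists()

    def test_vest_pipeline(self, tmp_path):
        import numpy as np
        from delaystand.signals import EVSConfig, VestibularCoupling, generate_emg, generate_evs
        fs = 500.0
        evs = generate_evs(EVSConfig(duration_s=30.0, fs=fs, target_rms=1.5, seed=1))
        tr = TrialRecord(fs=fs, time_s=np.arange(len(evs)) / fs, evs_ma=evs,
                         emg_au=generate_emg(
                             TrialRecord(fs=fs, time_s=np.arange(len(evs)) / fs),
                             evs, VestibularCoupling(fs=fs), seed=2))
        path = write_trial(tr, tmp_path / "vest.csv")
        runner = CliRunner()
        out = tmp_path / "vest.json"
        r = runner.invoke(main, ["vest", "--trials", str(path), "--nfft", "512",
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        res = json.loads(out.read_text())
        assert res["L"] == 29
        assert 0 < res["coherence_limit"] < 1

    def test_tfcoh_pipeline(self, tmp_path):
        runner = CliRunner()
        synth_dir = tmp_path / "s"
        r = runner.invoke(main, ["synth", "--experiment", "exp3", "--seed", "1",
                                 "--fs", "100", "--out", str(synth_dir)])
        assert r.exit_code == 0, r.output
        args = ["tfcoh", "--out", str(tmp_path / "map.json")]
        for f in sorted(synth_dir.glob("exp3*.csv")):
            args += ["--trials", str(f)]
        r = runner.invoke(main, args)
        assert r.exit_code == 0, r.output
        res = json.loads((tmp_path / "map.json").read_text())
        assert res["n_transitions"] >= 80
        assert len(res["frequencies_hz"]) == 40

    def test_percept_pipeline(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "synth"
        r = runner.invoke(main, ["synth", "--experiment", "exp2-percept",
                                 "--seed", "1", "--fs", "100", "--out", str(out)])
        assert r.exit_code == 0, r.output
        files = sorted(str(p) for p in out.glob("exp2-percept*.csv"))
        args = ["percept", "--out", str(tmp_path / "percept.json")]
        for f in files:
            args += ["--trials", f]
        r = runner.invoke(main, args)
        assert r.exit_code == 0, r.output
        res = json.loads((tmp_path / "percept.json").read_text())
        assert "threshold70_ms" in res
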