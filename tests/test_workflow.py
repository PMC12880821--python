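"""End-to-end orchestration: config validation, sweep runs, artifacts,
report rendering, frame I/O and the CLI contract.

Sweeps here run at reduced photon counts (a few thousand) -- enough to
exercise every stage deterministically without trend-resolving statistics.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml

from cipls import io as cio
from cipls.mosaic import MosaicFrame, render_mosaic
from cipls.phantom import make_sample_set, render_synthetic_frames
from cipls.workflow import (
    ConfigError,
    RunConfig,
    StageError,
    process_frames,
    report,
    run_sweep,
)


@pytest.fixture(scope="module")
def t1_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("t1run")
    cfg = RunConfig(out_dir=str(out), seed=5, n_photons=4000,
                    scene_shape=(64, 64))
    trend = run_sweep(cfg, "T1")
    return cfg, trend, out


class TestRunConfig:
    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "run.yaml"
        p.write_text(yaml.safe_dump({"mode": "simulate", "seed": 3,
                                     "n_photons": 2000}))
        cfg = RunConfig.from_yaml(p)
        assert cfg.seed == 3
        assert cfg.n_photons == 2000

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "run.yaml"
        p.write_text("mode: simulate\nbogus_key: 1\n")
        with pytest.raises(ConfigError, match="bogus_key"):
            RunConfig.from_yaml(p)

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig(mode="train")
        with pytest.raises(ConfigError):
            RunConfig(n_photons=10)
        with pytest.raises(ConfigError):
            RunConfig(noise_model="gaussian")

    def test_process_mode_requires_frames(self):
        with pytest.raises(ConfigError, match="frames"):
            RunConfig(mode="process")

    def test_hash_stable_and_sensitive(self):
        a = RunConfig(seed=1)
        b = RunConfig(seed=1)
        c = RunConfig(seed=2)
        assert a.config_hash() == b.config_hash()
        assert a.config_hash() != c.config_hash()


class TestT1Sweep:
    def test_four_rows_both_wavelengths(self, t1_run):
        _, trend, _ = t1_run
        assert len(trend.table) == 4
        np.testing.assert_array_equal(trend.swept_values, [0.0, 0.5, 1.0, 1.5])
        assert trend.table["t2_mm"].nunique() == 1
        assert trend.table[["mean_docp_617", "mean_docp_850"]].notna().all().all()

    def test_artifacts_written(self, t1_run):
        _, _, out = t1_run
        assert (out / "trends_t1.csv").exists()
        assert (out / "summaries_t1.csv").exists()
        assert (out / "runlog_t1.json").exists()
        for sid in ("1", "4", "5", "6"):
            assert (out / f"sample{sid}_617nm.tif").exists()
            assert (out / f"sample{sid}_docp_617nm.tif").exists()
            assert (out / f"sample{sid}_ddocp.tif").exists()

    def test_runlog_carries_hash_and_seeds(self, t1_run):
        cfg, _, out = t1_run
        log = json.loads((out / "runlog_t1.json").read_text())
        assert log["config_hash"] == cfg.config_hash()
        assert log["seed"] == cfg.seed
        assert set(log["samples"]) == {"1", "4", "5", "6"}

    def test_rerun_is_byte_identical(self, t1_run, tmp_path):
        cfg, _, out = t1_run
        cfg2 = RunConfig(out_dir=str(tmp_path / "again"), seed=cfg.seed,
                         n_photons=cfg.n_photons,
                         scene_shape=cfg.scene_shape)
        run_sweep(cfg2, "T1")
        a = (out / "trends_t1.csv").read_bytes()
        b = (tmp_path / "again" / "trends_t1.csv").read_bytes()
        assert a == b

    def test_recovered_docp_close_to_simulated(self, t1_run):
        """The imaging chain (render -> segment -> ROI mean) reproduces the
        simulated DOCP for every sample/wavelength."""
        _, trend, out = t1_run
        log = json.loads((out / "runlog_t1.json").read_text())
        for _, row in trend.table.iterrows():
            for wl, col in ((617, "mean_docp_617"), (850, "mean_docp_850")):
                sim = log["samples"][row["sample_id"]][str(wl)][
                    "simulated_docp"]
                assert row[col] == pytest.approx(sim, abs=0.02)


class TestT2Sweep:
    def test_three_rows(self, tmp_path):
        cfg = RunConfig(out_dir=str(tmp_path), seed=6, n_photons=4000,
                        scene_shape=(64, 64))
        trend = run_sweep(cfg, "T2")
        assert len(trend.table) == 3
        np.testing.assert_array_equal(trend.swept_values, [0.1, 0.5, 1.0])
        assert trend.table["t1_mm"].nunique() == 1

    def test_process_mode_missing_frame_aborts_with_sample_id(self, tmp_path):
        cfg = RunConfig(
            mode="process", out_dir=str(tmp_path), seed=1,
            frames={"2": {"617": str(tmp_path / "nope.tif"),
                          "850": str(tmp_path / "nope.tif")}},
        )
        with pytest.raises(StageError, match="sample 2"):
            run_sweep(cfg, "T2")


class TestProcessFrames:
    def test_single_sample_roundtrip(self, tmp_path):
        ph = make_sample_set()[3]
        frames = {}
        for wl in (617.0, 850.0):
            frame, _, _ = render_synthetic_frames(
                ph, wl, n_photons=4000, seed=9, shape=(64, 64))
            frames[wl] = frame
        res = process_frames(frames[617.0], frames[850.0], "4", 0.5, 1.0)
        assert len(res["summaries"]) == 2
        s617, s850 = res["summaries"]
        assert s617.wavelength_nm == 617.0
        assert s617.n_pixels > 100
        d_mean, _, _ = res["delta_roi_pixelwise"]
        assert d_mean == pytest.approx(s617.mean_docp - s850.mean_docp,
                                       abs=0.02)


class TestReport:
    def test_report_on_finished_run(self, t1_run):
        _, _, out = t1_run
        index = report(out)
        assert index.exists()
        assert (out / "trend_t1.png").exists()
        text = index.read_text()
        assert "T1 sweep" in text

    def test_report_is_idempotent(self, t1_run):
        _, _, out = t1_run
        a = report(out).read_text()
        b = report(out).read_text()
        assert a == b

    def test_empty_directory_warns(self, tmp_path):
        index = report(tmp_path)
        assert "Warnings" in index.read_text()


class TestFrameIO:
    def test_tiff_sidecar_roundtrip(self, tmp_path, rng):
        from conftest import random_physical_stokes

        field = random_physical_stokes(rng, n=16).reshape(4, 4, 4)
        frame = render_mosaic(field, gain=1000.0, noise_model="shot", seed=3,
                              wavelength_nm=850.0)
        cio.write_frame(frame, tmp_path / "f.tif")
        back = cio.read_frame(tmp_path / "f.tif")
        np.testing.assert_array_equal(back.data, frame.data)
        assert back.wavelength_nm == 850.0
        assert back.layout == frame.layout
        assert back.gain == frame.gain

    def test_missing_sidecar_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "orphan.tif",
                         np.zeros((4, 4), np.uint16))
        with pytest.raises(FileNotFoundError, match="sidecar"):
            cio.read_frame(tmp_path / "orphan.tif")

    def test_map_roundtrip_with_nan(self, tmp_path):
        m = np.array([[0.5, np.nan], [-0.25, 1.0]])
        cio.write_map(m, tmp_path / "m.tif")
        back = cio.read_map(tmp_path / "m.tif")
        np.testing.assert_allclose(back, m.astype(np.float32))
        assert (tmp_path / "m.png").exists()


class TestCli:
    def test_mie_table_subcommand(self, tmp_path):
        from click.testing import CliRunner

        from cipls.cli import main

        out = tmp_path / "table.csv"
        r = CliRunner().invoke(
            main, ["mie-table", "-d", "5.25", "-w", "617", "-o", str(out)]
        )
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out, comment="#")
        assert set(df.columns) == {"theta_rad", "m11", "m12", "m33", "m34"}
        assert len(df) == 181

    def test_sweep_command_and_exit_codes(self, tmp_path):
        from click.testing import CliRunner

        from cipls.cli import main

        cfgp = tmp_path / "run.yaml"
        cfgp.write_text(yaml.safe_dump({
            "mode": "simulate", "out_dir": str(tmp_path / "o"), "seed": 2,
            "n_photons": 2000, "scene_shape": [48, 48]}))
        r = CliRunner().invoke(main, ["sweep", "t2", "-c", str(cfgp)])
        assert r.exit_code == 0, r.output
        bad = tmp_path / "bad.yaml"
        bad.write_text("mode: nonsense\n")
        r2 = CliRunner().invoke(main, ["sweep", "t1", "-c", str(bad)])
        assert r2.exit_code == 2
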