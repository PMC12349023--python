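"""End-to-end file workflows and the command-line interface."""

import dataclasses
import json

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from algaecount import (
    annotate_image,
    count_cells,
    run_calibrate,
    run_count,
    run_simulate,
    run_validate,
)
from algaecount import calibration as cal
from algaecount.cli import main
from algaecount.detection import DetectionSet

from conftest import SMALL_DETECTION, SMALL_SCENE


@pytest.fixture()
def squares_dir(tmp_path):
    d = tmp_path / "squares"
    d.mkdir()
    rng = np.random.default_rng(0)
    for i, (h, w) in enumerate([(1218, 1222), (1225, 1230), (1216, 1221),
                                (1228, 1224), (1219, 1226)]):
        iio.imwrite(d / f"sq{i}.png", rng.integers(0, 255, (h, w), dtype=np.uint8))
    return d


@pytest.fixture()
def small_calibration_file(tmp_path):
    chamber = cal.ChamberSpec("scaled", square_side_mm=0.05, depth_mm=0.1)
    c = cal.build([SMALL_SCENE.grid_spacing_px], chamber,
                  SMALL_SCENE.height_px, SMALL_SCENE.width_px)
    path = tmp_path / "cal.json"
    cal.save_calibration(c, path)
    return path


class TestRunCalibrate:
    def test_artifact_and_report(self, squares_dir, tmp_path):
        out = tmp_path / "cal.json"
        report = tmp_path / "report.txt"
        c = run_calibrate(squares_dir, side_mm=0.05, depth_mm=0.1,
                          image_height_px=3024, image_width_px=4032,
                          out_path=out, report_path=report)
        assert out.exists() and report.exists()
        loaded = cal.load_calibration(out)
        assert loaded == c
        assert round(loaded.image_volume_mm3, 3) == 0.002
        assert "V_img" in report.read_text()

    def test_empty_squares_dir_fails(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(cal.CalibrationInputError):
            run_calibrate(empty, 0.05, 0.1, 100, 100, tmp_path / "c.json")

    def test_rerun_is_identical(self, squares_dir, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        run_calibrate(squares_dir, 0.05, 0.1, 3024, 4032, a)
        run_calibrate(squares_dir, 0.05, 0.1, 3024, 4032, b)
        assert a.read_text() == b.read_text()


class TestSimulateCountValidate:
    def test_full_round_trip(self, tmp_path, small_calibration_file):
        sim_dir = tmp_path / "sim"
        overrides = {
            f.name: getattr(SMALL_SCENE, f.name)
            for f in dataclasses.fields(SMALL_SCENE)
            if f.name != "seed"
        }
        overrides["n_cells"] = 18
        truth = run_simulate(sim_dir, n_images=3, seed=77, scene_overrides=overrides)
        assert (sim_dir / "truth.csv").exists()
        assert len(truth) == 3 * 18

        out_dir = tmp_path / "counts"
        summary = run_count(
            sim_dir, small_calibration_file, out_dir,
            dilution=1.0, params=SMALL_DETECTION,
        )
        per_image = pd.read_csv(out_dir / "per_image.csv")
        assert len(per_image) == 3
        assert (per_image["count"] == 18).all()
        assert summary["n_images"].iloc[0] == 3

        # validate counted vs truth counts
        truth_counts = truth.groupby("image_id").size().reset_index(name="count")
        truth_csv = tmp_path / "truth_counts.csv"
        truth_counts.to_csv(truth_csv, index=False)
        metrics = run_validate(out_dir / "per_image.csv", truth_csv,
                               tmp_path / "metrics.csv")
        assert metrics.set_index("metric").loc["mae", "value"] == 0.0

    def test_validate_with_masks(self, tmp_path, small_calibration_file):
        sim_dir = tmp_path / "sim"
        overrides = {
            f.name: getattr(SMALL_SCENE, f.name)
            for f in dataclasses.fields(SMALL_SCENE)
            if f.name != "seed"
        }
        run_simulate(sim_dir, n_images=2, seed=5, scene_overrides=overrides)
        out_dir = tmp_path / "counts"
        run_count(sim_dir, small_calibration_file, out_dir, params=SMALL_DETECTION)
        pred = pd.read_csv(out_dir / "per_image.csv")[["image_id", "count"]]
        pred_csv = tmp_path / "pred.csv"
        pred.to_csv(pred_csv, index=False)
        truth_counts = (
            pd.read_csv(sim_dir / "truth.csv").groupby("image_id").size()
            .reset_index(name="count")
        )
        truth_csv = tmp_path / "truth.csv"
        truth_counts.to_csv(truth_csv, index=False)
        metrics = run_validate(
            pred_csv, truth_csv, tmp_path / "m.csv",
            pred_masks_dir=out_dir, truth_masks_dir=sim_dir,
        ).set_index("metric")
        assert metrics.loc["iou_mean", "value"] >= 0.9

    def test_validate_id_mismatch_lists_offenders(self, tmp_path):
        pd.DataFrame({"image_id": ["a", "b"], "count": [1, 2]}).to_csv(
            tmp_path / "p.csv", index=False
        )
        pd.DataFrame({"image_id": ["a", "c"], "count": [1, 2]}).to_csv(
            tmp_path / "t.csv", index=False
        )
        with pytest.raises(ValueError, match="c"):
            run_validate(tmp_path / "p.csv", tmp_path / "t.csv", tmp_path / "m.csv")

    def test_count_empty_dir_fails(self, tmp_path, small_calibration_file):
        empty = tmp_path / "none"
        empty.mkdir()
        with pytest.raises(FileNotFoundError):
            run_count(empty, small_calibration_file, tmp_path / "out")


class TestAnnotate:
    def test_empty_set_leaves_image_unchanged(self, small_scene):
        dset = DetectionSet((), small_scene.params.height_px, small_scene.params.width_px)
        out = annotate_image(small_scene.image, dset)
        assert np.array_equal(out, small_scene.image)

    def test_overlay_count_matches_detections(self, small_scene):
        dset = count_cells(small_scene.image, SMALL_DETECTION)
        out = annotate_image(small_scene.image, dset)
        assert not np.array_equal(out, small_scene.image)
        # strokes are pure red; unchanged elsewhere
        changed = np.any(out != small_scene.image, axis=2)
        assert np.all(out[changed] == [255, 0, 0])
        # each drawn circle produces one red connected ring: count them
        from skimage import measure

        rings = measure.label(changed, connectivity=2).max()
        assert rings == dset.count


class TestCli:
    def test_calibrate_command(self, squares_dir, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cal.json"
        result = runner.invoke(main, [
            "calibrate", "--squares", str(squares_dir), "--side-mm", "0.05",
            "--depth-mm", "0.1", "--image-width", "4032", "--image-height", "3024",
            "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert "V_img" in result.output
        assert json.loads(out.read_text())["image_volume_mm3"] == pytest.approx(
            0.00204, rel=1e-2
        )

    def test_count_missing_calibration_fails(self, tmp_path):
        runner = CliRunner()
        img_dir = tmp_path / "imgs"
        img_dir.mkdir()
        result = runner.invoke(main, [
            "count", "--images", str(img_dir), "--calibration",
            str(tmp_path / "missing.json"), "--out", str(tmp_path / "o"),
        ])
        assert result.exit_code != 0

    def test_simulate_and_count_commands(self, tmp_path, small_calibration_file):
        runner = CliRunner()
        import yaml

        cfg = {
            f.name: getattr(SMALL_SCENE, f.name)
            for f in dataclasses.fields(SMALL_SCENE)
            if f.name != "seed"
        }
        cfg["n_cells"] = 12
        cfg_path = tmp_path / "scene.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        sim_dir = tmp_path / "sim"
        result = runner.invoke(main, [
            "simulate", "--out", str(sim_dir), "--n-images", "2", "--seed", "9",
            "--config", str(cfg_path),
        ])
        assert result.exit_code == 0, result.output
        result = runner.invoke(main, [
            "count", "--images", str(sim_dir), "--calibration",
            str(small_calibration_file), "--out", str(tmp_path / "o"),
            "--min-radius", "9", "--max-radius", "17", "--min-dist", "24",
        ])
        assert result.exit_code == 0, result.output
        per_image = pd.read_csv(tmp_path / "o" / "per_image.csv")
        assert (per_image["count"] == 12).all()
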