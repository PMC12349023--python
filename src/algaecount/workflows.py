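"""File-level workflows tying calibration, detection, quantification and
validation together; the CLI in :mod:`algaecount.cli` is a thin wrapper
around these functions so everything here is scriptable from Python."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibration as cal
from . import metrics as met
from .detection import DetectionParams, DetectionSet, count_cells, detections_to_mask
from .quantification import (
    ImageConcentration,
    SampleMeta,
    concentration_from_count,
    aggregate_sample,
)

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def _list_images(directory: str | Path) -> list[Path]:
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"not a directory: {d}")
    return sorted(p for p in d.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)


def run_calibrate(
    squares_dir: str | Path,
    side_mm: float,
    depth_mm: float,
    image_height_px: int,
    image_width_px: int,
    out_path: str | Path,
    report_path: str | Path | None = None,
    chamber_name: str = "custom",
    side_tolerance_mm: float = 0.0,
) -> cal.Calibration:
    """Measure etalon crops, build the calibration, write artifact + report."""
    crops = _list_images(squares_dir)
    if not crops:
        raise cal.CalibrationInputError(f"no etalon crop images in {squares_dir}")
    lengths = cal.edge_lengths_from_crops(crops)
    chamber = cal.ChamberSpec(
        name=chamber_name,
        square_side_mm=side_mm,
        depth_mm=depth_mm,
        side_tolerance_mm=side_tolerance_mm,
    )
    calibration = cal.build(lengths, chamber, image_height_px, image_width_px)
    report, _ = cal.build_calibration_report(
        calibration, artifact_path=out_path, report_path=report_path
    )
    logger.info("image volume V_img = %.6g mm^3", calibration.image_volume_mm3)
    return calibration


def annotate_image(image: np.ndarray, dset: DetectionSet) -> np.ndarray:
    """Draw detection circle outlines (red) on a copy of the image."""
    from skimage.draw import circle_perimeter

    out = np.asarray(image).copy()
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    for d in dset.detections:
        rr, cc = circle_perimeter(
            int(round(d.center_y_px)),
            int(round(d.center_x_px)),
            int(round(d.radius_px)),
            shape=out.shape[:2],
        )
        out[rr, cc] = (255, 0, 0)
    return out


def run_count(
    images_dir: str | Path,
    calibration_path: str | Path,
    out_dir: str | Path,
    dilution: float = 1.0,
    sample_id: str = "sample",
    params: DetectionParams | None = None,
    overlays: bool = False,
) -> pd.DataFrame:
    """Count cells in every image of a directory and report concentrations.

    Writes ``per_image.csv`` (image_id, count, cells_per_ml at full
    precision), ``summary.csv`` (sample-level mean/median/SD rounded to whole
    cells/mL), per-image detection masks, and optional annotated overlays.
    Unreadable files are skipped with a warning.
    """
    import imageio.v3 as iio

    calibration = cal.load_calibration(calibration_path)
    # masks/overlays written next to source images are not samples
    paths = [
        p for p in _list_images(images_dir)
        if not p.stem.endswith(("_mask", "_overlay"))
    ]
    if not paths:
        raise FileNotFoundError(f"no images found in {images_dir}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = DetectionParams()

    rows = []
    per_image: list[ImageConcentration] = []
    for path in paths:
        try:
            image = iio.imread(path)
        except Exception as exc:  # pragma: no cover - depends on file system
            logger.warning("skipping unreadable image %s: %s", path.name, exc)
            continue
        dset = count_cells(image, params)
        conc = concentration_from_count(
            dset.count, calibration.image_volume_mm3, dilution
        )
        per_image.append(ImageConcentration(path.stem, dset.count, conc))
        rows.append({"image_id": path.stem, "count": dset.count, "cells_per_ml": conc})
        mask = detections_to_mask(dset)
        iio.imwrite(out / f"{path.stem}_mask.png", (mask * 255).astype(np.uint8))
        if overlays:
            iio.imwrite(out / f"{path.stem}_overlay.png", annotate_image(image, dset))

    if not per_image:
        raise RuntimeError("no image could be processed")
    per_image_df = pd.DataFrame(rows)
    per_image_df.to_csv(out / "per_image.csv", index=False)

    meta = SampleMeta(sample_id=sample_id, dilution=dilution, calibration_ref=calibration)
    sample = aggregate_sample(per_image, meta)
    summary = pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "dilution": dilution,
                "n_images": sample.n_images,
                "mean_cells_per_ml": int(round(sample.mean_cells_per_ml)),
                "median_cells_per_ml": int(round(sample.median_cells_per_ml)),
                "std_cells_per_ml": int(round(sample.std_cells_per_ml)),
            }
        ]
    )
    summary.to_csv(out / "summary.csv", index=False)
    logger.info(
        "sample %s: mean %.3g cells/mL over %d images",
        sample_id, sample.mean_cells_per_ml, sample.n_images,
    )
    return summary


def run_simulate(
    out_dir: str | Path,
    n_images: int,
    seed: int,
    scene_overrides: dict | None = None,
    concentration: float | None = None,
    calibration_path: str | Path | None = None,
    dilution: float = 1.0,
) -> pd.DataFrame:
    """Write a deterministic synthetic corpus: images, truth CSV, masks.

    Without a concentration, renders ``n_images`` scenes with the configured
    fixed ``n_cells``; with ``--concentration`` and a calibration, per-image
    counts are Poisson at the calibrated expected count.
    """
    import imageio.v3 as iio

    from . import synthetic as syn

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    overrides = dict(scene_overrides or {})
    overrides["seed"] = seed
    base = syn.SceneParams(**overrides)

    if concentration is not None:
        if calibration_path is None:
            raise ValueError("--concentration requires a calibration artifact")
        calibration = cal.load_calibration(calibration_path)
        scenes = syn.generate_sample(
            concentration, n_images, calibration, dilution, base
        )
    else:
        scenes = [
            syn.generate_scene(
                dataclasses.replace(base, seed=syn._child_seed(seed, i))
            )
            for i in range(n_images)
        ]

    truth_rows = []
    for i, scene in enumerate(scenes):
        image_id = f"scene_{i:03d}"
        iio.imwrite(out / f"{image_id}.png", scene.image)
        iio.imwrite(
            out / f"{image_id}_mask.png", (scene.truth_mask * 255).astype(np.uint8)
        )
        for (x, y), r in zip(scene.true_centers, scene.true_radii):
            truth_rows.append(
                {"image_id": image_id, "center_x": x, "center_y": y, "radius": r}
            )
    truth = pd.DataFrame(
        truth_rows, columns=["image_id", "center_x", "center_y", "radius"]
    )
    truth.to_csv(out / "truth.csv", index=False)
    (out / "scene_params.json").write_text(
        json.dumps(dataclasses.asdict(base), indent=2)
    )
    return truth


def run_validate(
    pred_path: str | Path,
    truth_path: str | Path,
    out_path: str | Path,
    pred_masks_dir: str | Path | None = None,
    truth_masks_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Score predicted counts (and optionally masks) against ground truth.

    Input CSVs need ``image_id`` and ``count`` columns; if both carry a
    ``cells_per_ml`` column, percentage differences and their summary are
    added. Mask directories are matched by ``<image_id>_mask.png`` name.
    """
    import imageio.v3 as iio

    pred = pd.read_csv(pred_path)
    truth = pd.read_csv(truth_path)
    for df, name in ((pred, "prediction"), (truth, "truth")):
        if "image_id" not in df.columns or "count" not in df.columns:
            raise ValueError(f"{name} CSV needs image_id and count columns")
    pred_ids = set(pred["image_id"])
    truth_ids = set(truth["image_id"])
    if pred_ids != truth_ids:
        raise ValueError(
            "image id mismatch between prediction and truth: "
            f"only-in-prediction={sorted(pred_ids - truth_ids)}, "
            f"only-in-truth={sorted(truth_ids - pred_ids)}"
        )
    merged = pred.merge(truth, on="image_id", suffixes=("_pred", "_true")).sort_values(
        "image_id"
    )

    rows = [{"metric": "mae", "value": met.mae(merged["count_true"], merged["count_pred"])}]
    if len(merged) >= 2 and merged["count_true"].std() > 0 and merged["count_pred"].std() > 0:
        rows.append(
            {"metric": "pearson_r",
             "value": met.pearson(merged["count_true"], merged["count_pred"])}
        )

    if "cells_per_ml_pred" in merged.columns and "cells_per_ml_true" in merged.columns:
        pct = [
            met.percentage_difference(t, p)
            for t, p in zip(merged["cells_per_ml_true"], merged["cells_per_ml_pred"])
        ]
        mean_, median_, std_ = met.column_summary(pct)
        rows += [
            {"metric": "pct_difference_mean", "value": mean_},
            {"metric": "pct_difference_median", "value": median_},
            {"metric": "pct_difference_std", "value": std_},
        ]

    if pred_masks_dir is not None and truth_masks_dir is not None:
        ious, area_errors = [], []
        for image_id in merged["image_id"]:
            pm = iio.imread(Path(pred_masks_dir) / f"{image_id}_mask.png") > 0
            tm = iio.imread(Path(truth_masks_dir) / f"{image_id}_mask.png") > 0
            ious.append(met.iou(pm, tm))
            if pm.any() and tm.any():
                area_errors.append(met.mean_area_error(pm, tm))
        rows.append({"metric": "iou_mean", "value": float(np.mean(ious))})
        rows += [
            {"metric": f"iou:{image_id}", "value": v}
            for image_id, v in zip(merged["image_id"], ious)
        ]
        if area_errors:
            rows.append(
                {"metric": "mean_area_error_pct", "value": float(np.mean(area_errors))}
            )

    result = pd.DataFrame(rows)
    result.to_csv(out_path, index=False)
    return result
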