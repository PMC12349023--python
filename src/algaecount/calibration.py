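"""Pixel-to-metric calibration from etalon chamber squares.

A hemocytometer (counting chamber) carries an etched grid of squares whose
side length ``l`` is stated by the manufacturer. Cropping a few grid squares
out of microscope images and measuring their edges in pixels yields the
conversion factor ``s = l / p`` (mm per pixel, with ``p`` the mean measured
edge in px). Combined with the chamber depth ``h`` this gives the volume of
suspension covered by one full image,

    V_img = (s * PH) * (s * PW) * h   [mm^3],

which is what turns a per-image cell count into a concentration. The
calibration is performed once per equipment setup (chamber type,
magnification, camera resolution).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

RECOMMENDED_MIN_SQUARES = 5


class CalibrationInputError(ValueError):
    """Raised when calibration inputs are missing or empty."""


class InvalidCropError(ValueError):
    """Raised when an etalon crop is not a usable 2-D image."""


@dataclass(frozen=True)
class ChamberSpec:
    """Manufacturer geometry of a counting chamber.

    Parameters
    ----------
    name : str
        Chamber label, e.g. ``"goryaev"`` or ``"neubauer-improved"``.
    square_side_mm : float
        Side length of the grid square used as etalon (mm).
    depth_mm : float
        Depth of the chamber under the cover slip (mm).
    side_tolerance_mm : float, optional
        Manufacturing tolerance of the square side (mm).
    small_square_area_mm2 : float, optional
        Area of the counting square for the manual-count formula.
    """

    name: str
    square_side_mm: float
    depth_mm: float
    side_tolerance_mm: float = 0.0
    small_square_area_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.square_side_mm <= 0:
            raise ValueError("square_side_mm must be positive")
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be positive")
        if self.side_tolerance_mm < 0:
            raise ValueError("side_tolerance_mm must be >= 0")
        if self.small_square_area_mm2 is not None and self.small_square_area_mm2 <= 0:
            raise ValueError("small_square_area_mm2 must be positive when given")


@dataclass(frozen=True)
class EtalonStats:
    """Summary of pixel-length measurements of etalon square edges."""

    lengths_px: tuple[float, ...]
    n_measurements: int
    mean_px: float
    std_px: float


@dataclass(frozen=True)
class Calibration:
    """One equipment setup's pixel scale and per-image suspension volume."""

    conversion_factor_mm_per_px: float
    image_height_px: int
    image_width_px: int
    image_volume_mm3: float
    chamber: ChamberSpec
    etalon: EtalonStats

    def __post_init__(self) -> None:
        if self.conversion_factor_mm_per_px <= 0:
            raise ValueError("conversion factor must be positive")
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise ValueError("image dimensions must be >= 1 px")
        expected = image_volume(
            self.conversion_factor_mm_per_px,
            self.image_height_px,
            self.image_width_px,
            self.chamber.depth_mm,
        )
        if not math.isclose(self.image_volume_mm3, expected, rel_tol=1e-9):
            raise ValueError(
                f"image_volume_mm3={self.image_volume_mm3!r} inconsistent with "
                f"(s*PH)*(s*PW)*h={expected!r}"
            )


def edge_lengths_from_crops(crops: Iterable) -> list[float]:
    """Measure etalon square edges from operator-cropped square images.

    Each crop is assumed to be snipped so its borders coincide with one
    chamber square's edges; its own width and height in pixels therefore
    *are* two measurements of the square side. Both are kept — a slightly
    tilted grid makes them differ, and using both captures that spread.

    Parameters
    ----------
    crops : iterable of array or path
        2-D or 3-D image arrays, or paths to image files.

    Returns
    -------
    list of float
        ``[width_1, height_1, width_2, height_2, ...]`` in pixels.
    """
    import imageio.v3 as iio

    lengths: list[float] = []
    n = 0
    for crop in crops:
        if isinstance(crop, (str, Path)):
            crop = iio.imread(crop)
        arr = np.asarray(crop)
        if arr.ndim == 3:
            arr = arr[..., 0]
        if arr.ndim != 2:
            raise InvalidCropError(f"crop has unexpected ndim={arr.ndim}")
        h, w = arr.shape
        if h == 0 or w == 0:
            raise InvalidCropError("crop has a zero dimension")
        lengths.extend([float(w), float(h)])
        n += 1
    if n == 0:
        raise CalibrationInputError("no etalon crops provided")
    return lengths


def summarize_etalon(lengths_px: Sequence[float]) -> EtalonStats:
    """Mean and population standard deviation of edge measurements.

    Fewer than five squares (ten edge measurements) triggers a logged
    warning: measuring at least five squares spread over the chamber is
    the recommended practice, not a hard requirement.
    """
    arr = np.asarray(list(lengths_px), dtype=float)
    if arr.size == 0:
        raise CalibrationInputError("no edge measurements provided")
    if np.any(arr <= 0):
        raise ValueError("edge measurements must be positive")
    n_squares = arr.size / 2
    if n_squares < RECOMMENDED_MIN_SQUARES:
        logger.warning(
            "only %.0f etalon square(s) contributed (%d measurements); "
            "at least %d squares from different chamber regions are recommended",
            math.ceil(n_squares), arr.size, RECOMMENDED_MIN_SQUARES,
        )
    return EtalonStats(
        lengths_px=tuple(arr.tolist()),
        n_measurements=int(arr.size),
        mean_px=float(arr.mean()),
        std_px=float(arr.std(ddof=0)),
    )


def conversion_factor(stats: EtalonStats, chamber: ChamberSpec) -> float:
    """Conversion factor ``s = l / p`` in mm per pixel, unrounded."""
    if stats.mean_px <= 0:
        raise ValueError("mean edge length must be positive")
    if chamber.square_side_mm <= 0:
        raise ValueError("chamber square side must be positive")
    return chamber.square_side_mm / stats.mean_px


def image_volume(
    s: float, image_height_px: float, image_width_px: float, depth_mm: float
) -> float:
    """Suspension volume under one full image, ``(s*PH)*(s*PW)*h`` in mm^3."""
    if s <= 0 or image_height_px <= 0 or image_width_px <= 0 or depth_mm <= 0:
        raise ValueError("all image-volume arguments must be positive")
    return (s * image_height_px) * (s * image_width_px) * depth_mm


def build(
    lengths_px: Sequence[float],
    chamber: ChamberSpec,
    image_height_px: int,
    image_width_px: int,
) -> Calibration:
    """Assemble a full :class:`Calibration` from raw edge measurements."""
    stats = summarize_etalon(lengths_px)
    s = conversion_factor(stats, chamber)
    v = image_volume(s, image_height_px, image_width_px, chamber.depth_mm)
    return Calibration(
        conversion_factor_mm_per_px=s,
        image_height_px=int(image_height_px),
        image_width_px=int(image_width_px),
        image_volume_mm3=v,
        chamber=chamber,
        etalon=stats,
    )


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def calibration_report(calibration: Calibration) -> str:
    """Human-readable calibration report.

    Displays the conversion factor at 2 significant figures and the image
    volume at 1 significant figure, the conventional reporting precision;
    the underlying :class:`Calibration` carries full precision.
    """
    cal = calibration
    et = cal.etalon
    ch = cal.chamber
    lines = [
        "Calibration report",
        "==================",
        f"Chamber: {ch.name} (square side {ch.square_side_mm} ± "
        f"{ch.side_tolerance_mm} mm, depth {ch.depth_mm} mm)",
        f"Etalon measurements: n = {et.n_measurements}, "
        f"mean = {et.mean_px:.0f} px, std = {et.std_px:.0f} px (population)",
        f"Conversion factor s = l/p = {ch.square_side_mm}/{et.mean_px:.0f} = "
        f"{_round_sig(cal.conversion_factor_mm_per_px, 2):.1e} mm/px",
        f"Image size: {cal.image_width_px} x {cal.image_height_px} px (W x H)",
        f"Image volume V_img = (s*PH)*(s*PW)*h = "
        f"{_round_sig(cal.image_volume_mm3, 1):g} mm^3 "
        f"(unrounded {cal.image_volume_mm3:.6g})",
    ]
    return "\n".join(lines)


def to_dict(calibration: Calibration) -> dict:
    """JSON-serializable artifact with full precision."""
    cal = calibration
    return {
        "chamber": asdict(cal.chamber),
        "etalon": {
            "lengths_px": list(cal.etalon.lengths_px),
            "n_measurements": cal.etalon.n_measurements,
            "mean_px": cal.etalon.mean_px,
            "std_px": cal.etalon.std_px,
        },
        "conversion_factor_mm_per_px": cal.conversion_factor_mm_per_px,
        "image_height_px": cal.image_height_px,
        "image_width_px": cal.image_width_px,
        "image_volume_mm3": cal.image_volume_mm3,
    }


def from_dict(d: dict) -> Calibration:
    chamber = ChamberSpec(**d["chamber"])
    et = d["etalon"]
    etalon = EtalonStats(
        lengths_px=tuple(et["lengths_px"]),
        n_measurements=et["n_measurements"],
        mean_px=et["mean_px"],
        std_px=et["std_px"],
    )
    return Calibration(
        conversion_factor_mm_per_px=d["conversion_factor_mm_per_px"],
        image_height_px=d["image_height_px"],
        image_width_px=d["image_width_px"],
        image_volume_mm3=d["image_volume_mm3"],
        chamber=chamber,
        etalon=etalon,
    )


def build_calibration_report(
    calibration: Calibration,
    artifact_path: str | Path | None = None,
    report_path: str | Path | None = None,
) -> tuple[str, dict]:
    """Emit the auto-built calibration report and machine-readable artifact.

    Returns ``(report_text, artifact_dict)``; writes them to the given paths
    when provided. The JSON artifact round-trips losslessly through
    :func:`load_calibration`.
    """
    report = calibration_report(calibration)
    artifact = to_dict(calibration)
    if artifact_path is not None:
        Path(artifact_path).write_text(json.dumps(artifact, indent=2))
    if report_path is not None:
        Path(report_path).write_text(report + "\n")
    return report, artifact


def save_calibration(calibration: Calibration, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_dict(calibration), indent=2))


def load_calibration(path: str | Path) -> Calibration:
    return from_dict(json.loads(Path(path).read_text()))
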