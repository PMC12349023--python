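"""Counts to cells/mL, per-sample aggregation, and dilution guidance.

Two equivalent routes to a concentration:

* manual hemocytometer route, ``N = a * 10^3 / (h * S)`` with ``a`` the mean
  count per chamber square of area ``S`` (mm^2) and depth ``h`` (mm);
* automated route, ``N = a_img * D * 10^3 / V_img`` with ``a_img`` the count
  over one full image, ``V_img`` the calibrated image volume (mm^3) and
  ``D >= 1`` the dilution applied during sample preparation.

The ``10^3`` converts mm^3 to mL. When the image footprint covers exactly
one chamber square the two routes agree. Per-image concentrations are kept
at full precision; rounding to whole cells/mL happens only when a sample
summary is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import Calibration

logger = logging.getLogger(__name__)

MM3_TO_ML = 1e3  # mm^3 -> mL count scaling in the concentration formulas

#: Target per-image count window: below ~10 cells the estimate gets noisy,
#: above ~60 cells overlap starts to defeat both manual and automated counting.
MIN_CELLS_PER_IMAGE = 10
MAX_CELLS_PER_IMAGE = 60


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    dilution: float
    calibration_ref: Calibration

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


@dataclass(frozen=True)
class ImageConcentration:
    image_id: str
    count: int
    concentration_cells_per_ml: float


@dataclass(frozen=True)
class SampleConcentration:
    per_image: tuple[ImageConcentration, ...]
    mean_cells_per_ml: float
    median_cells_per_ml: float
    std_cells_per_ml: float
    n_images: int


def manual_concentration(
    mean_cells_per_square: float, depth_mm: float, square_area_mm2: float
) -> float:
    """Classical hemocytometer formula ``N = a * 10^3 / (h * S)``."""
    if depth_mm <= 0 or square_area_mm2 <= 0:
        raise ValueError("chamber depth and square area must be positive")
    if mean_cells_per_square < 0:
        raise ValueError("cell count cannot be negative")
    return mean_cells_per_square * MM3_TO_ML / (depth_mm * square_area_mm2)


def concentration_from_count(
    count: float, image_volume_mm3: float, dilution: float = 1.0
) -> float:
    """Automated formula ``N = a_img * D * 10^3 / V_img`` (cells/mL)."""
    if image_volume_mm3 <= 0:
        raise ValueError("image volume must be positive")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if count < 0:
        raise ValueError("cell count cannot be negative")
    return count * dilution * MM3_TO_ML / image_volume_mm3


def expected_count(
    true_concentration: float, image_volume_mm3: float, dilution: float = 1.0
) -> float:
    """Expected per-image count for a known concentration (inverse formula)."""
    if image_volume_mm3 <= 0:
        raise ValueError("image volume must be positive")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    if true_concentration < 0:
        raise ValueError("concentration cannot be negative")
    return true_concentration * image_volume_mm3 / (MM3_TO_ML * dilution)


def aggregate_sample(
    per_image: Sequence[ImageConcentration], meta: SampleMeta
) -> SampleConcentration:
    """Mean/median/population-SD of per-image concentrations.

    The mean is the headline estimate: slide zones are technically
    equivalent, and on real validation data the mean does not do worse than
    the median. Both are reported for comparison.
    """
    if len(per_image) == 0:
        raise ValueError("at least one image concentration is required")
    vals = np.array([ic.concentration_cells_per_ml for ic in per_image], dtype=float)
    return SampleConcentration(
        per_image=tuple(per_image),
        mean_cells_per_ml=float(vals.mean()),
        median_cells_per_ml=float(np.median(vals)),
        std_cells_per_ml=float(vals.std(ddof=0)),
        n_images=len(per_image),
    )


#: 1-2-5 preferred-number series used for dilution recommendations.
_DILUTION_SERIES_BASE = (1, 2, 5)


def recommend_dilution(
    estimated_concentration: float, image_volume_mm3: float
) -> float:
    """Smallest dilution from {1, 2, 5, 10, 20, 50, ...} keeping the
    expected per-image count at or below the countable maximum.

    Logs a warning when even undiluted imaging is expected to yield fewer
    than the minimum recommended cells per image.
    """
    if estimated_concentration <= 0:
        raise ValueError("estimated concentration must be positive")
    decade = 1
    while True:
        for base in _DILUTION_SERIES_BASE:
            d = base * decade
            exp = expected_count(estimated_concentration, image_volume_mm3, d)
            if exp <= MAX_CELLS_PER_IMAGE:
                if d == 1 and exp < MIN_CELLS_PER_IMAGE:
                    logger.warning(
                        "expected count %.1f per image is below %d even "
                        "undiluted; consider capturing extra images",
                        exp, MIN_CELLS_PER_IMAGE,
                    )
                return float(d)
        decade *= 10
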