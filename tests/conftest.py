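"""Shared fixtures: scaled-down scene configurations and detection params.

Two reference configurations are used throughout the suite:

* ``med`` — 1024x768 frames with cell radii ~21 px in [15, 28]; the
  validation resolution for detection-quality experiments.
* ``small`` — 640x480 frames with cell radii ~13 px in [9, 17]; cheap
  enough for replicated end-to-end concentration experiments.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pytest

from algaecount import DetectionParams, SceneParams, generate_scene

# the Eq.-4 advisory (min_dist < 2*max_radius) fires by design in the
# scaled-down configs; keep it out of test output noise
logging.getLogger("algaecount.detection").setLevel(logging.ERROR)


MED_SCENE = SceneParams(
    height_px=768,
    width_px=1024,
    grid_spacing_px=306.0,
    grid_line_width_px=4,
    n_cells=30,
    radius_mean_px=21.0,
    radius_std_px=3.0,
    radius_min_px=15.0,
    radius_max_px=28.0,
    min_separation_px=2.2 * 28.0,
)

MED_DETECTION = DetectionParams(min_radius_px=15, max_radius_px=28, min_dist_px=40)

SMALL_SCENE = SceneParams(
    height_px=480,
    width_px=640,
    grid_spacing_px=205.0,
    grid_line_width_px=3,
    n_cells=30,
    radius_mean_px=13.0,
    radius_std_px=2.0,
    radius_min_px=9.0,
    radius_max_px=17.0,
    min_separation_px=2.2 * 17.0,
)

SMALL_DETECTION = DetectionParams(min_radius_px=9, max_radius_px=17, min_dist_px=24)


def child_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % 2**31)


@pytest.fixture(scope="session")
def med_scene():
    """One deterministic clean medium scene."""
    return generate_scene(dataclasses.replace(MED_SCENE, seed=7, n_cells=25))


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic clean small scene."""
    return generate_scene(dataclasses.replace(SMALL_SCENE, seed=11, n_cells=20))
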