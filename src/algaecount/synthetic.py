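"""Synthetic hemocytometer imagery with exact ground truth.

Renders what a microscope camera sees over a counting chamber: a light
background crossed by the dark etched grid, with green near-circular cells
scattered over it. Every scene carries its exact truth (centers, radii,
count, rasterized mask), recorded *before* any degradation is applied, so
the detection and quantification chain can be validated end to end without
any external data.

Emulated real-data features: grid lines, cell size dispersion (truncated
normal radii), optional clumping (touching groups standing in for
agglomerated cells), defocus blur, uneven illumination, overexposure,
salt-and-pepper noise, and non-cell foreign blobs. Not emulated: optical
texture inside cells, diffraction halos, non-circular cell outlines.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .calibration import Calibration
from .detection import disks_mask
from .quantification import expected_count


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested separation."""


@dataclass(frozen=True)
class SceneParams:
    """Scene geometry, population and degradation settings.

    Defaults emulate the reference high-magnification setup: a 4032x3024 px
    frame over a Goryaev-type grid whose square edge spans about 1222 px,
    with cell radii in the 15-100 px detection range.
    """

    height_px: int = 3024
    width_px: int = 4032
    background_rgb: tuple[int, int, int] = (232, 233, 226)
    grid_spacing_px: float = 1222.0
    grid_line_width_px: int = 10
    grid_rgb: tuple[int, int, int] = (95, 100, 95)
    n_cells: int = 30
    radius_mean_px: float = 45.0
    radius_std_px: float = 12.0
    radius_min_px: float = 15.0
    radius_max_px: float = 100.0
    min_separation_px: float = 220.0
    cell_rgb_mean: tuple[int, int, int] = (70, 150, 90)
    cell_rgb_jitter: float = 15.0
    clump_fraction: float = 0.0
    clump_size: int = 3
    illumination_gradient_amplitude: float = 0.0
    blur_sigma_px: float = 0.0
    salt_pepper_prob: float = 0.0
    n_foreign_objects: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.radius_min_px <= self.radius_mean_px <= self.radius_max_px):
            raise ValueError("need radius_min <= radius_mean <= radius_max")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be >= 0")
        if not (0.0 <= self.clump_fraction <= 1.0):
            raise ValueError("clump_fraction must be in [0, 1]")
        if self.clump_size < 2:
            raise ValueError("clump_size must be >= 2")
        if not (0.0 <= self.illumination_gradient_amplitude < 1.0):
            raise ValueError("illumination gradient amplitude must be in [0, 1)")
        if self.blur_sigma_px < 0:
            raise ValueError("blur_sigma_px must be >= 0")
        if not (0.0 <= self.salt_pepper_prob < 1.0):
            raise ValueError("salt_pepper_prob must be in [0, 1)")
        if self.n_cells < 0 or self.n_foreign_objects < 0:
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class DegradationSpec:
    """Image-only corruptions; ground truth is never touched."""

    blur_sigma_px: float = 0.0
    illumination_gradient_amplitude: float = 0.0
    overexposure_fraction: float = 0.0
    salt_pepper_prob: float = 0.0
    n_foreign_objects: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_sigma_px < 0 or self.salt_pepper_prob < 0:
            raise ValueError("degradation magnitudes must be >= 0")
        if not (0.0 <= self.overexposure_fraction <= 1.0):
            raise ValueError("overexposure_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # HxWx3 uint8
    true_centers: tuple[tuple[float, float], ...]  # (x, y)
    true_radii: tuple[float, ...]
    truth_mask: np.ndarray  # HxW bool
    true_count: int
    params: SceneParams


def _truncated_normal(
    rng: np.random.Generator, mean: float, std: float, lo: float, hi: float, n: int
) -> np.ndarray:
    if std == 0:
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = rng.normal(mean, std, size=2 * (n - filled) + 8)
        good = draws[(draws >= lo) & (draws <= hi)]
        take = min(good.size, n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


_MAX_TRIES_PER_CELL = 2000


def _place_cells(
    rng: np.random.Generator, p: SceneParams, radii: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample centers; returns (xs, ys).

    Cells are split into singles and clumps of ``clump_size``. Singles and
    whole clumps keep pairwise center distance >= min_separation; members
    within a clump touch (center gap ~ 0.9 * sum of radii).
    """
    n = p.n_cells
    n_clumped = int(round(p.clump_fraction * n))
    groups: list[list[int]] = []
    idx = 0
    while idx < n_clumped:
        size = min(p.clump_size, n_clumped - idx)
        if size == 1 and groups:
            groups[-1].append(idx)  # fold a lone remainder into the last clump
            idx += 1
            continue
        groups.append(list(range(idx, idx + size)))
        idx += size
    singles = list(range(n_clumped, n))

    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    placed_other: list[int] = []  # indices placed in *previous* groups/singles

    def far_enough(x: float, y: float, against: list[int]) -> bool:
        for j in against:
            if (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < p.min_separation_px**2:
                return False
        return True

    def inside(x: float, y: float, r: float) -> bool:
        return r <= x <= p.width_px - 1 - r and r <= y <= p.height_px - 1 - r

    def place_one(i: int, against: list[int]) -> None:
        r = radii[i]
        for _ in range(_MAX_TRIES_PER_CELL):
            x = rng.uniform(r, p.width_px - 1 - r)
            y = rng.uniform(r, p.height_px - 1 - r)
            if far_enough(x, y, against):
                xs[i], ys[i] = x, y
                return
        raise PlacementError(
            f"could not place cell {i} at min separation "
            f"{p.min_separation_px} px in a {p.width_px}x{p.height_px} frame"
        )

    for group in groups:
        anchor = group[0]
        placed_members: list[int] = []
        for _ in range(_MAX_TRIES_PER_CELL):
            place_one(anchor, placed_other)
            placed_members = [anchor]
            ok = True
            for m in group[1:]:
                r = radii[m]
                success = False
                for _ in range(_MAX_TRIES_PER_CELL):
                    base = placed_members[rng.integers(len(placed_members))]
                    ang = rng.uniform(0, 2 * np.pi)
                    d = 0.9 * (radii[base] + r)
                    x = xs[base] + d * np.cos(ang)
                    y = ys[base] + d * np.sin(ang)
                    if inside(x, y, r) and far_enough(x, y, placed_other):
                        xs[m], ys[m] = x, y
                        placed_members.append(m)
                        success = True
                        break
                if not success:
                    ok = False
                    break
            if ok:
                break
        else:
            raise PlacementError("could not place a clump within the frame")
        placed_other.extend(placed_members)

    for i in singles:
        place_one(i, placed_other)
        placed_other.append(i)
    return xs, ys


def _render_grid(img: np.ndarray, p: SceneParams) -> None:
    color = np.array(p.grid_rgb, dtype=float)
    spacing = p.grid_spacing_px
    half = p.grid_line_width_px / 2.0
    phase = spacing / 2.0
    for axis, size in ((0, p.height_px), (1, p.width_px)):
        pos = phase
        while pos < size:
            lo = max(0, int(round(pos - half)))
            hi = min(size, int(round(pos + half)))
            if hi > lo:
                if axis == 0:
                    img[lo:hi, :, :] = color
                else:
                    img[:, lo:hi, :] = color
            pos += spacing


def _render_cells(
    img: np.ndarray,
    rng: np.random.Generator,
    p: SceneParams,
    xs: np.ndarray,
    ys: np.ndarray,
    radii: np.ndarray,
) -> None:
    h, w = img.shape[:2]
    for x, y, r in zip(xs, ys, radii):
        color = np.array(p.cell_rgb_mean, float) + rng.normal(
            0, p.cell_rgb_jitter, size=3
        )
        color = np.clip(color, 0, 255)
        x0 = max(0, int(np.floor(x - r - 2)))
        x1 = min(w, int(np.ceil(x + r + 3)))
        y0 = max(0, int(np.floor(y - r - 2)))
        y1 = min(h, int(np.ceil(y + r + 3)))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.sqrt((yy - y) ** 2 + (xx - x) ** 2)
        alpha = np.clip(r + 0.5 - d, 0.0, 1.0)  # 1 px anti-aliased rim
        patch = img[y0:y1, x0:x1, :]
        patch[...] = patch * (1 - alpha[..., None]) + color * alpha[..., None]


def _render_foreign_objects(
    img: np.ndarray, rng: np.random.Generator, n_objects: int
) -> None:
    """Irregular non-green blobs emulating debris/substrate particles."""
    from skimage import draw as skdraw

    h, w = img.shape[:2]
    for _ in range(n_objects):
        cx = rng.uniform(0.1 * w, 0.9 * w)
        cy = rng.uniform(0.1 * h, 0.9 * h)
        base_r = rng.uniform(0.01, 0.04) * min(h, w)
        ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        wobble = 1.0 + 0.45 * np.sin(ang * rng.integers(2, 5) + rng.uniform(0, 6.28))
        rad = base_r * wobble * rng.uniform(0.8, 1.2, size=ang.size)
        rr, cc = skdraw.polygon(cy + rad * np.sin(ang), cx + rad * np.cos(ang), img.shape[:2])
        color = np.array([rng.uniform(90, 150), rng.uniform(70, 110), rng.uniform(50, 90)])
        img[rr, cc, :] = color


def _apply_illumination(img: np.ndarray, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    h, w = img.shape[:2]
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    proj = xx * np.cos(theta) + yy * np.sin(theta)
    u = (proj - proj.min()) / max(np.ptp(proj), 1e-12)
    factor = 1.0 + amplitude * (2.0 * u - 1.0)
    return img * factor[..., None]


def _apply_salt_pepper(img: np.ndarray, rng: np.random.Generator, prob: float) -> np.ndarray:
    h, w = img.shape[:2]
    noise = rng.random((h, w))
    out = img.copy()
    out[noise < prob / 2.0] = 0.0
    out[(noise >= prob / 2.0) & (noise < prob)] = 255.0
    return out


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one scene; deterministic for a fixed ``params.seed``.

    Cells (and their mask) are recorded as truth before blur, illumination,
    noise or foreign objects are painted, so degradations only affect what
    the detector sees, never the answer key.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    radii = _truncated_normal(
        rng, p.radius_mean_px, p.radius_std_px, p.radius_min_px, p.radius_max_px,
        p.n_cells,
    )
    if p.n_cells > 0:
        xs, ys = _place_cells(rng, p, radii)
    else:
        xs = np.empty(0)
        ys = np.empty(0)

    img = np.empty((p.height_px, p.width_px, 3), dtype=float)
    img[...] = np.array(p.background_rgb, float)
    _render_grid(img, p)
    _render_cells(img, rng, p, xs, ys, radii)

    centers = tuple((float(x), float(y)) for x, y in zip(xs, ys))
    mask = disks_mask(centers, radii, (p.height_px, p.width_px))

    deg = DegradationSpec(
        blur_sigma_px=p.blur_sigma_px,
        illumination_gradient_amplitude=p.illumination_gradient_amplitude,
        salt_pepper_prob=p.salt_pepper_prob,
        n_foreign_objects=p.n_foreign_objects,
        seed=p.seed,
    )
    img = _degrade_array(img, deg, rng)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticScene(
        image=image,
        true_centers=centers,
        true_radii=tuple(float(r) for r in radii),
        truth_mask=mask,
        true_count=p.n_cells,
        params=p,
    )


def _degrade_array(
    img: np.ndarray, spec: DegradationSpec, rng: np.random.Generator
) -> np.ndarray:
    out = img.astype(float)
    if spec.n_foreign_objects > 0:
        _render_foreign_objects(out, rng, spec.n_foreign_objects)
    if spec.illumination_gradient_amplitude > 0:
        out = _apply_illumination(out, rng, spec.illumination_gradient_amplitude)
    if spec.overexposure_fraction > 0:
        # push the top of the dynamic range into saturation
        out = out / (1.0 - spec.overexposure_fraction)
    if spec.blur_sigma_px > 0:
        out = ndimage.gaussian_filter(out, sigma=(spec.blur_sigma_px, spec.blur_sigma_px, 0))
    if spec.salt_pepper_prob > 0:
        out = _apply_salt_pepper(out, rng, spec.salt_pepper_prob)
    return out


def degrade(scene: SyntheticScene, spec: DegradationSpec | dict) -> SyntheticScene:
    """Apply image-only corruptions to an existing scene.

    Accepts a :class:`DegradationSpec` or a dict of its field names; an
    unrecognized field name raises ``ValueError``. Ground truth (centers,
    radii, count, mask) is carried over unchanged.
    """
    if isinstance(spec, dict):
        valid = {f.name for f in dataclasses.fields(DegradationSpec)}
        unknown = set(spec) - valid
        if unknown:
            raise ValueError(f"unknown degradation mode(s): {sorted(unknown)}")
        spec = DegradationSpec(**spec)
    rng = np.random.default_rng(spec.seed)
    img = _degrade_array(scene.image.astype(float), spec, rng)
    return SyntheticScene(
        image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        true_centers=scene.true_centers,
        true_radii=scene.true_radii,
        truth_mask=scene.truth_mask,
        true_count=scene.true_count,
        params=scene.params,
    )


def _child_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % 2**31)


def generate_sample(
    true_concentration: float,
    n_images: int,
    calibration: Calibration,
    dilution: float = 1.0,
    base_params: SceneParams | None = None,
) -> list[SyntheticScene]:
    """A sample: several images of one suspension at a known concentration.

    Per-image true counts are Poisson with mean given by the calibrated
    expected count (cells are well mixed, so counts over equal sub-volumes
    are Poisson). Scene seeds derive deterministically from the base seed
    and image index.
    """
    if true_concentration < 0:
        raise ValueError("concentration cannot be negative")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    p = base_params if base_params is not None else SceneParams()
    lam = expected_count(true_concentration, calibration.image_volume_mm3, dilution)
    count_rng = np.random.default_rng(np.random.SeedSequence([p.seed, 0x5A17]))
    counts = count_rng.poisson(lam, size=n_images)
    scenes = []
    for i, c in enumerate(counts):
        sp = dataclasses.replace(p, n_cells=int(c), seed=_child_seed(p.seed, i))
        scenes.append(generate_scene(sp))
    return scenes
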