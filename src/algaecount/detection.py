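"""Cell detection: CLAHE green enhancement, grayscale, median blur, circle Hough.

Chlorella vulgaris cells are near-spherical, so detection approximates each
cell as a circle and counts circles over the whole image footprint. The
chain is:

1. spectrum correction — contrast-limited adaptive histogram equalization
   (CLAHE) of the green channel only, exploiting the chlorophyll absorption
   signature of the cells;
2. luminance grayscale, Y = 0.299 R + 0.587 G + 0.114 B;
3. median blur (default 3x3) to kill salt-and-pepper sensor noise;
4. circle Hough transform over the expected radius range, with a minimum
   center-to-center distance enforced by non-maximum suppression.

``sensitivity`` is the accumulator-evidence threshold: the normalized Hough
accumulator scores a candidate circle by the fraction of its perimeter
supported by edge pixels, and a candidate is kept when that fraction is at
least ``sensitivity`` percent. Lower sensitivity therefore admits more
circles (recall up, precision down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, exposure
from skimage.feature import canny, peak_local_max
from skimage.transform import hough_circle, hough_line, hough_line_peaks

logger = logging.getLogger(__name__)

#: Accumulator floor for collecting candidate peaks; sensitivities of 10 and
#: above share one candidate pool, which keeps edge claiming independent of
#: the sensitivity filter.
_CANDIDATE_FLOOR = 0.10

#: A genuine circle is supported all around its perimeter, while straight
#: edges (grid lines) tangent to a candidate support only short arcs. A
#: candidate must have supporting edge pixels in at least this fraction of
#: twelve 30-degree sectors.
_ANGULAR_BINS = 12
_MIN_ANGULAR_COVERAGE = 0.5


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the detection chain.

    Defaults target ~4k images of the reference setup where cells span
    15–100 px in radius; scale the radius bounds and ``min_dist_px`` when
    working at other magnifications/resolutions.
    """

    min_radius_px: int = 15
    max_radius_px: int = 100
    min_dist_px: int = 100
    sensitivity: float = 30.0
    median_kernel: int = 3
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    # circle-transform internals the defaults of which are conventional:
    radius_step: int = 1
    edge_sigma: float = 2.0
    gradient_threshold: float = 100.0
    refine: bool = True
    # chamber grid lines are long straight edges; edge pixels lying on a
    # line supported by at least line_threshold_frac * min(H, W) collinear
    # edge pixels are masked out before circle voting
    suppress_lines: bool = True
    line_threshold_frac: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.min_radius_px < self.max_radius_px):
            raise ValueError("need 0 < min_radius_px < max_radius_px")
        if self.min_dist_px <= 0:
            raise ValueError("min_dist_px must be positive")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.radius_step < 1:
            raise ValueError("radius_step must be >= 1")
        # advisory geometric constraint: proper separation of adjacent cells
        # asks for min_dist >= 2*max_radius; the reference defaults violate
        # it, so it is logged rather than enforced.
        if self.min_dist_px < 2 * self.max_radius_px:
            logger.warning(
                "min_dist_px=%d < 2*max_radius_px=%d: adjacent large cells "
                "may be merged by non-maximum suppression",
                self.min_dist_px, 2 * self.max_radius_px,
            )


@dataclass(frozen=True)
class Detection:
    """One detected circle; x is the column, y the row, 0-based."""

    center_x_px: float
    center_y_px: float
    radius_px: float
    evidence: float = 0.0


@dataclass(frozen=True)
class DetectionSet:
    """All circle detections for one image."""

    detections: tuple[Detection, ...]
    image_height_px: int
    image_width_px: int

    @property
    def count(self) -> int:
        return len(self.detections)


def _as_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim == 2:  # grayscale promoted by channel replication
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be at least 1x1")
    return arr


def enhance_green(
    image: np.ndarray, clahe_clip: float = 2.0, clahe_tiles: tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Replace the green channel by its CLAHE-equalized version.

    Red and blue are passed through untouched. ``clahe_clip`` follows the
    common histogram-bin convention (clip limit as a multiple of the uniform
    bin height over 256 bins); internally it maps to skimage's fractional
    clip limit ``clahe_clip / 256``.
    """
    arr = _as_rgb(image).astype(np.uint8)
    green = arr[..., 1]
    if green.min() == green.max():
        return arr.copy()  # flat channel: nothing to equalize
    ty, tx = clahe_tiles
    kernel = (max(1, arr.shape[0] // ty), max(1, arr.shape[1] // tx))
    eq = exposure.equalize_adapthist(
        green, kernel_size=kernel, clip_limit=clahe_clip / 256.0
    )
    out = arr.copy()
    out[..., 1] = np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    return out


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale Y = 0.299 R + 0.587 G + 0.114 B, rounded, uint8."""
    arr = _as_rgb(image).astype(np.float64)
    y = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def denoise_median(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with reflecting borders; kernel 1 is the identity."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("denoise_median expects a 2-D grayscale image")
    if kernel == 1:
        return arr.copy()
    return ndimage.median_filter(arr, size=kernel, mode="reflect")


def _kasa_fit(ys: np.ndarray, xs: np.ndarray) -> tuple[float, float, float] | None:
    """Algebraic least-squares circle fit (Kasa). Returns (cx, cy, r)."""
    if ys.size < 6:
        return None
    A = np.column_stack([xs, ys, np.ones_like(xs, dtype=float)])
    b = xs.astype(float) ** 2 + ys.astype(float) ** 2
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if r2 <= 0:
        return None
    return float(cx), float(cy), float(np.sqrt(r2))


def _suppress_line_edges(edges: np.ndarray, min_support: float) -> np.ndarray:
    """Mask edge pixels lying on long straight lines (the chamber grid).

    Uses the standard (deterministic) Hough line transform; every edge pixel
    within 2.5 px of a line supported by at least ``min_support`` collinear
    edge pixels is dropped. Cell-boundary arcs crossing a grid line lose
    only the short arc inside that band.
    """
    hspace, angles, dists = hough_line(edges)
    _, peak_angles, peak_dists = hough_line_peaks(
        hspace, angles, dists, threshold=min_support
    )
    if len(peak_angles) == 0:
        return edges
    out = edges.copy()
    ey, ex = np.nonzero(out)
    drop = np.zeros(ey.size, dtype=bool)
    for theta, rho in zip(peak_angles, peak_dists):
        drop |= np.abs(ex * np.cos(theta) + ey * np.sin(theta) - rho) <= 2.5
    out[ey[drop], ex[drop]] = False
    return out


def detect_circles(image: np.ndarray, params: DetectionParams) -> DetectionSet:
    """Circle Hough detection with greedy non-maximum suppression.

    Works on gradient magnitude (canny edges), so no assumption is made on
    whether cells are darker or lighter than the background. Accumulator
    peaks are processed best-evidence-first with greedy ``min_dist_px``
    suppression (ties broken by row, column, radius). Each surviving circle
    is then re-scored by the fraction of its perimeter supported by edge
    pixels *not already claimed* by a stronger circle: a spurious candidate
    whose support is borrowed from arcs of neighbouring cells collapses
    once those cells have claimed their own edges. The ``sensitivity``
    filter applies to this re-scored support as a final pure filter, so the
    detection set at a higher sensitivity is exactly a subset of the set at
    a lower one. When ``refine`` is on, each reported circle is re-fit by
    least squares to its unclaimed perimeter edge pixels, giving sub-pixel
    centers and radii.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("detect_circles expects a 2-D grayscale image")
    h, w = arr.shape
    edges = canny(
        arr.astype(float),
        sigma=params.edge_sigma,
        low_threshold=params.gradient_threshold / 2.0,
        high_threshold=params.gradient_threshold,
    )
    if params.suppress_lines and edges.any():
        edges = _suppress_line_edges(
            edges, params.line_threshold_frac * min(h, w)
        )
    radii = np.arange(
        params.min_radius_px, params.max_radius_px + 1, params.radius_step
    )
    threshold = params.sensitivity / 100.0
    # candidate floor independent of sensitivity (for sensitivity >= 10),
    # keeping the candidate pool -- and hence edge claiming -- threshold-free
    floor = min(threshold, _CANDIDATE_FLOOR)

    candidates: list[tuple[float, int, int, int]] = []  # (evidence, y, x, r)
    # bound accumulator memory to ~200 MB: chunk * H * W float64 at a time
    chunk = int(np.clip(2e8 // (h * w * 8), 1, 16))
    for i in range(0, len(radii), chunk):
        rs = radii[i : i + chunk]
        acc = hough_circle(edges, rs, normalize=True)
        for j, r in enumerate(rs):
            plane = acc[j]
            peaks = peak_local_max(
                plane, min_distance=1, threshold_abs=floor, exclude_border=False
            )
            for y, x in peaks:
                candidates.append((float(plane[y, x]), int(y), int(x), int(r)))

    # greedy NMS: best accumulator evidence first, ties by (row, column,
    # radius); a spatial hash with cell size min_dist keeps this linear
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    kept: list[tuple[float, int, int, int]] = []
    min_d2 = float(params.min_dist_px) ** 2
    cell = max(int(params.min_dist_px), 1)
    buckets: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for cand in candidates:
        _, y, x, _ = cand
        gy, gx = y // cell, x // cell
        clear = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for ky, kx in buckets.get((gy + dy, gx + dx), ()):
                    if (y - ky) ** 2 + (x - kx) ** 2 < min_d2:
                        clear = False
                        break
                if not clear:
                    break
            if not clear:
                break
        if clear:
            kept.append(cand)
            buckets.setdefault((gy, gx), []).append((y, x))

    ey, ex = np.nonzero(edges)
    claimed = np.zeros(ey.size, dtype=bool)
    dets = []
    for _, y, x, r in kept:
        cx, cy, rad = float(x), float(y), float(r)
        support = 0.0
        if ey.size:
            d = np.sqrt((ey - y) ** 2.0 + (ex - x) ** 2.0)
            # scoring band matches the accumulator's one-pixel ring (plus
            # half-pixel center quantization)
            usable = (np.abs(d - r) <= 0.75) & ~claimed
            support = float(usable.sum() / (2.0 * np.pi * r))
            angles = np.arctan2(ey[usable] - y, ex[usable] - x)
            bins = np.unique(
                ((angles + np.pi) / (2 * np.pi) * _ANGULAR_BINS).astype(int)
                % _ANGULAR_BINS
            )
            if bins.size < _MIN_ANGULAR_COVERAGE * _ANGULAR_BINS:
                support = 0.0
            if params.refine:
                fit_sel = (np.abs(d - r) <= 2.0) & ~claimed
                fit = _kasa_fit(ey[fit_sel], ex[fit_sel])
                if fit is not None:
                    fx, fy, fr = fit
                    # accept the refinement only if it stays near the Hough peak
                    if abs(fx - x) <= 3 and abs(fy - y) <= 3 and abs(fr - r) <= 3:
                        cx, cy, rad = fx, fy, fr
            # claim a wider annulus so weaker overlapping candidates cannot
            # reuse this circle's edge
            claimed |= np.abs(d - r) <= 2.5
        if support < threshold:
            continue
        rad = float(np.clip(rad, params.min_radius_px, params.max_radius_px))
        if 0 <= cx <= w - 1 and 0 <= cy <= h - 1:
            dets.append(Detection(cx, cy, rad, evidence=support))
    return DetectionSet(tuple(dets), image_height_px=h, image_width_px=w)


def disks_mask(
    centers_xy: np.ndarray | list, radii: np.ndarray | list, shape: tuple[int, int]
) -> np.ndarray:
    """Union of filled rasterized disks; the shared rasterizer for predicted
    and ground-truth masks so that identical circle parameters give
    identical masks."""
    mask = np.zeros(shape, dtype=bool)
    for (x, y), r in zip(centers_xy, radii):
        rr, cc = draw.disk((float(y), float(x)), float(r), shape=shape)
        mask[rr, cc] = True
    return mask


def detections_to_mask(dset: DetectionSet) -> np.ndarray:
    """Binary mask as the union of the detection disks."""
    centers = [(d.center_x_px, d.center_y_px) for d in dset.detections]
    radii = [d.radius_px for d in dset.detections]
    return disks_mask(centers, radii, (dset.image_height_px, dset.image_width_px))


def count_cells(image: np.ndarray, params: DetectionParams | None = None) -> DetectionSet:
    """Full chain: green CLAHE -> grayscale -> median blur -> circle Hough."""
    if params is None:
        params = DetectionParams()
    rgb = enhance_green(_as_rgb(image), params.clahe_clip, params.clahe_tiles)
    gray = to_grayscale(rgb)
    gray = denoise_median(gray, params.median_kernel)
    return detect_circles(gray, params)
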