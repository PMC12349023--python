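# Methods

## Measurement model

A counting chamber (hemocytometer) holds a suspension layer of known depth
`h` beneath a cover slip, over a grid of squares of known side `l`. The
classical estimate counts cells per grid square of area `S`:

    N = a · 10³ / (h · S)        [cells/mL]

`algaecount` replaces per-square counting with full-frame counting. The
grid square serves as a length etalon: cropping a square out of a
microscope image and measuring its edge in pixels gives the scale
`s = l / p` (mm/px, with `p` the mean of the edge measurements), and the
volume imaged by one full `PW × PH` frame is

    V_img = (s · PH) · (s · PW) · h        [mm³]

so a per-image count `a_img` under dilution `D ≥ 1` converts to

    N = a_img · D · 10³ / V_img.

The 10³ factor converts mm³ to mL. Both routes agree exactly when the
image footprint equals one grid square (`s²·PH·PW = S`); this identity is
tested. `V_img` is carried unrounded; reports display `s` at 2 significant
figures and `V_img` at 1, the conventional reporting precision.

### Calibration conventions

- Each cropped square contributes **both** its width and its height as
  edge measurements; a slightly tilted grid makes them differ, and the
  spread is part of the measurement uncertainty.
- Spread is always the **population** standard deviation (divide by n),
  matching the convention of the per-sample summaries.
- Fewer than five measured squares triggers a warning, not an error:
  five squares spread over the chamber is recommended practice, not a
  mathematical requirement.
- Chamber depth is an explicit user input. Catalogue depths for the same
  chamber type vary between sources (0.02 mm vs 0.1 mm for Goryaev-type
  chambers, depending on model), so the package never infers depth from a
  chamber name.

## Detection chain

1. **Green-channel CLAHE.** Chlorophyll gives cells their strongest
   contrast in the green channel; contrast-limited adaptive histogram
   equalization is applied to green only, red and blue pass through
   bit-identical. `clahe_clip` follows the 256-bin convention (default
   2.0, i.e. a fractional clip limit of 2/256); tiles default to 8×8.
2. **Luminance grayscale** `Y = 0.299R + 0.587G + 0.114B`, rounded to
   uint8.
3. **Median blur** (default 3×3, reflecting borders) against
   salt-and-pepper sensor noise.
4. **Circle Hough transform** over radii `[min_radius_px, max_radius_px]`
   (defaults 15 and 100 px for ~4k frames at 40–60× magnification; scale
   them with resolution). Edges come from a Canny detector (sigma 2,
   gradient threshold 100 — conventional values, configurable). The
   transform operates on gradients, so no assumption is made about cells
   being darker or lighter than the background.

Candidate selection is deterministic and proceeds in four stages:

- **Grid-line suppression.** The chamber grid is the dominant source of
  circle false positives: two straight edges meeting at a grid corner can
  mimic ~30% perimeter support. Before circle voting, a standard Hough
  *line* transform finds lines supported by at least
  `line_threshold_frac · min(H, W)` collinear edge pixels (default 0.4),
  and edge pixels within 2.5 px of such a line are masked out. Cell arcs
  crossing a grid line lose only the short arc inside that band.
- **Non-maximum suppression.** Accumulator peaks (normalized to perimeter
  fraction) are processed best-first, ties broken by (row, column,
  radius); a peak is kept if its center is at least `min_dist_px` from
  every kept center. The advisory geometric rule `min_dist ≥ 2·max_radius`
  is logged when violated but not enforced, because the reference defaults
  (dist 100, max radius 100) themselves violate it.
- **Edge-claiming re-scoring.** Each surviving circle, strongest first,
  is re-scored by the fraction of its perimeter covered by edge pixels
  *not already claimed* by a stronger circle (band ±0.75 px, matching the
  accumulator ring), then claims a ±2.5 px annulus. A "ghost" candidate
  whose support is borrowed from the arcs of neighbouring cells collapses
  once those cells have claimed their edges. Support must also span at
  least 6 of 12 angular sectors, rejecting candidates supported by a few
  tangent arcs only.
- **Sensitivity filter.** `sensitivity` (default 30) is the evidence
  threshold in percent of perimeter: a circle is reported when its
  re-scored support is ≥ `sensitivity/100`. Lower sensitivity → more
  recall. Because the candidate pool, suppression and claiming are all
  computed at a fixed internal floor (accumulator ≥ 0.10), the filter is a
  pure final cut, and the detection set at a higher sensitivity is exactly
  a subset of the set at a lower one (property-tested).

Kept circles are refined by an algebraic least-squares (Kasa) circle fit
to their unclaimed perimeter edge pixels, giving sub-pixel centers and
radii; the refinement is accepted only within 3 px of the Hough peak, and
radii are clipped back to the configured bounds. A detection is kept
whenever its center lies inside the image. Coordinates are 0-based,
x = column, y = row.

Masks are the union of filled rasterized disks at the detected centers
and radii; prediction and ground truth share one rasterizer, so identical
circle parameters give identical masks.

## Quantification

Per-image concentrations are kept at full precision; only per-sample
summary values are rounded to whole cells/mL at reporting time. The
per-sample headline estimate is the **mean** over images (slide zones are
exchangeable; on real validation data the mean is not worse than the
median), reported alongside median and population SD.

`recommend_dilution` walks the 1–2–5 preferred-number series and returns
the smallest dilution keeping the expected per-image count at or below 60
(cells begin to overlap above that), warning when even undiluted imaging
is expected to yield fewer than 10 cells per image.

## Validation metrics

- Count MAE is normalized by the number of images, `(1/N)·Σ|xᵢ−yᵢ|`, as
  the name "mean absolute error" requires.
- Mask IoU (Jaccard index) defines two empty masks as perfect agreement
  (1.0) and exactly one empty as 0.0; real comparisons never hit either.
- "Cell area error" is the relative error of the *mean* per-cell area, in
  percent: π·r² for circle-parameterized inputs, mean connected-component
  pixel count for masks. (The reference column reports a name only; this
  is the package's reconstruction.)
- Percentage difference uses the expert value as denominator:
  `|automatic − expert| / expert · 100`.
- The clumping trend is an OLS fit of percentage (or absolute) error on
  the clump rate; a positive slope reproduces the expected degradation of
  counting as cells agglomerate.

## Synthetic scenes

The generator renders what validation needs, not photorealism: a light
background, dark grid lines at the configured spacing, and anti-aliased
green-dominant disks with per-cell color jitter. Radii follow a truncated
normal (resampled into `[radius_min, radius_max]`). Placement is rejection
sampling with a bounded retry budget (hard error on infeasible packing,
never silent under-filling). A `clump_fraction` of the cells is placed in
touching groups of `clump_size` (center gap ≈ 0.9·(r₁+r₂)), standing in
for acid-induced agglomeration whose real geometry is irregular. Truth
(centers, radii, count, mask) is recorded **before** any degradation;
blur, illumination ramps, overexposure, salt-and-pepper noise and
non-green foreign blobs alter the image only.

Per-sample imagery draws per-image counts from a Poisson law at the
calibrated expected count — the canonical model for a well-mixed
suspension — with scene seeds derived deterministically from the base
seed and image index. Identical parameters give bit-identical scenes.

The default scene mirrors the reference high-magnification setup
(4032×3024 px, grid pitch ≈ 1222 px, radii 15–100 px). What passing tests
on these scenes shows: the geometry → volume → concentration arithmetic,
and the detector's behaviour on well-separated circular objects over a
grid, including its degradation under clumping, blur and uneven
illumination. What they cannot show: performance on real optics (texture
inside cells, halos, debris that mimics cell shape), non-circular or
out-of-focus morphology, and color distributions of a particular camera.

## Test problem sizes

Replicated experiments use scaled-down frames so the suite stays fast
while keeping ≥ 10 px cell radii (below which the circle transform loses
localization): detection-quality runs use 1024×768 scenes with radii
~21 px in [15, 28] (100 seeded scenes, 10–60 cells each, separation
2.2·max radius), and end-to-end concentration experiments use 640×480
scenes with radii ~13 px in [9, 17] (50 replicates of 10-image samples at
an expected 30 cells per image, plus 200 count-only replicates). The full
radius range [15, 100] cannot pack 60 separated cells into 1024×768, so
radii scale with the frame.

A note on the 10-image round trip: with 10 images at an expected count of
30, pure Poisson sampling alone puts the sample mean outside ±10% of truth
in ~8% of replicates; the ≥90%-of-replicates pass criterion therefore
operates close to its own statistical floor even for a perfect detector.

## Known limitations

- Touching cells closer than `min_dist_px` merge into one detection;
  clump splitting is out of scope, and counts under heavy agglomeration
  are biased low (by design the error grows with clump rate).
- The angular-coverage requirement (≥ 180° of supported perimeter) can
  reject heavily occluded cells inside dense clusters.
- Radius bounds are specified in pixels; they must be re-derived when
  magnification or resolution changes (the calibration's `s` gives the
  px↔µm mapping).
- Foreign objects of near-circular shape in the cell size range are
  counted as cells; pre-filtering the sample remains the remedy.
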