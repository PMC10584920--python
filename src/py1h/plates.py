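"""Colony-array image quantification for 1536-format readout plates.

The image stage turns a photographed readout plate into per-colony
measurements. The pipeline is: (1) ``preprocess`` converts to a
single-channel signal image rescaled to [0, 1] with larger values meaning
stronger reporter (beta-galactosidase) signal; (2) ``crop_plate`` trims to
the bounding box of a fixed-threshold foreground mask; (3) ``detect_grid``
locates the 32 x 48 grid of colony centers from smoothed projections of an
enhanced foreground mask, exploiting the equidistant pinning of the colony
array so that missing colonies are tolerated by least-squares
extrapolation; (4) ``segment`` thresholds each grid cell locally (Otsu,
largest connected component, hole filling); (5) ``measure`` reports each
position's area (foreground pixel count) and mean foreground intensity.

Each strain occupies a 2 x 2 quadruplicate block of the 1536 grid, so a
plate carries 384 strain positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "PlateImage",
    "GridSpec",
    "ColonyMeasurement",
    "preprocess",
    "crop_plate",
    "detect_grid",
    "segment",
    "measure",
    "measure_plate",
]

GRID_ROWS = 32
GRID_COLS = 48
DEFAULT_CROP_THRESHOLD = 0.1


@dataclass
class PlateImage:
    """Single-channel signal image in [0, 1]; larger = stronger signal."""

    pixels: np.ndarray
    plate_id: str = ""
    readout_day: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("plate image must be a non-empty 2-D array")


@dataclass
class GridSpec:
    """Fitted equidistant 32 x 48 colony grid.

    ``centers_y``/``centers_x`` hold the fitted center coordinate of every
    grid row/column (pixels, 0-based). Grid position (r, c) belongs to
    quadruplicate block (r // 2, c // 2).
    """

    rows: int
    cols: int
    centers_y: np.ndarray
    centers_x: np.ndarray
    spacing_y: float
    spacing_x: float

    def center(self, r: int, c: int) -> tuple[float, float]:
        return float(self.centers_y[r]), float(self.centers_x[c])

    def block_of(self, r: int, c: int) -> tuple[int, int]:
        return r // 2, c // 2


@dataclass(frozen=True)
class ColonyMeasurement:
    row: int
    col: int
    area: int
    intensity: float  # NaN when missing
    flag: str = ""    # "", "missing", "touching", "low_confidence"


def preprocess(raw: np.ndarray, invert: bool = False) -> PlateImage:
    """Convert a raw 1- or 3-channel image to a rescaled signal image.

    RGB images are reduced to luminance. With ``invert=True`` the signal is
    ``1 - luminance`` (light plates with dark/blue colonies). Rescaling to
    [0, 1] is guarded: constant images pass through unchanged.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError("expected an RGB(A) image")
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    elif arr.ndim != 2:
        raise ValueError("expected a 1- or 3-channel image")
    if np.issubdtype(np.asarray(raw).dtype, np.integer):
        arr = arr / np.iinfo(np.asarray(raw).dtype).max
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    if invert:
        arr = 1.0 - arr
    return PlateImage(pixels=arr)


def crop_plate(
    image: PlateImage, threshold: float = DEFAULT_CROP_THRESHOLD
) -> tuple[PlateImage, tuple[int, int]]:
    """Crop to the bounding box of the fixed-threshold foreground mask.

    Returns the cropped image and the (row, col) offsets of its origin in
    the input. Idempotent. Raises ``ValueError("blank_plate")`` when no
    pixel reaches the threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    mask = image.pixels >= threshold
    if not mask.any():
        raise ValueError("blank_plate: no foreground pixel at threshold")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    return (
        PlateImage(image.pixels[r0:r1, c0:c1], image.plate_id, image.readout_day),
        (r0, c0),
    )


def _tile_background(pixels: np.ndarray, tile: int = 16) -> np.ndarray:
    """Smooth background field from per-tile low percentiles.

    A low percentile per tile ignores the colonies (which never fill a
    tile), unlike a plain blur whose estimate bright colonies inflate.
    """
    h, w = pixels.shape
    ph = (-h) % tile
    pw = (-w) % tile
    padded = np.pad(pixels, ((0, ph), (0, pw)), mode="edge")
    tiles = padded.reshape(padded.shape[0] // tile, tile, padded.shape[1] // tile, tile)
    coarse = np.percentile(tiles, 20, axis=(1, 3))
    coarse = ndimage.gaussian_filter(coarse, sigma=1.0)
    zoomed = ndimage.zoom(coarse, tile, order=1)
    return zoomed[:h, :w]


def _foreground_mask(pixels: np.ndarray) -> np.ndarray:
    """Colony mask: tile-percentile background subtraction followed by a
    noise-adaptive threshold (5 robust sd above the residual background,
    floored at 0.03 for noise-free images)."""
    resid = pixels - _tile_background(pixels)
    med = float(np.median(resid))
    smad = 1.4826 * float(np.median(np.abs(resid - med)))
    thr = max(0.03, med + 5.0 * smad)
    return np.clip(resid, 0, None) > thr


def _axis_centers(projection: np.ndarray, n_expected: int, min_peaks: int) -> np.ndarray:
    """Fit ``n_expected`` equidistant centers to the peaks of a projection.

    Peaks are gradient zero crossings (+ to -) of the smoothed projection;
    the spacing is estimated as the median inter-peak distance and the
    origin/spacing refined by least squares on the peak positions.
    """
    from scipy.signal import find_peaks

    proj = projection.astype(float)
    if proj.max() <= 0:
        raise ValueError("no_grid_detected: empty projection")
    # first pass: rough peaks to estimate spacing
    rough, _ = find_peaks(proj, prominence=0.1 * proj.max())
    if rough.size >= 2:
        spacing0 = float(np.median(np.diff(rough)))
    else:
        spacing0 = proj.size / n_expected
    window = max(3, int(round(spacing0 / 2)) | 1)
    kernel = np.ones(window) / window
    smooth = np.convolve(proj, kernel, mode="same")
    # gradient zero crossings (rising to falling) are the colony centers
    grad = np.gradient(smooth)
    sign = np.sign(grad)
    crossings = np.nonzero((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    peaks = np.array(
        [c for c in crossings if smooth[c] > 0.15 * smooth.max()], dtype=float
    )
    # refine each crossing to sub-pixel by local center of mass
    half = max(2, window // 2)
    refined = []
    for c in peaks:
        lo = int(max(0, c - half))
        hi = int(min(proj.size, c + half + 1))
        w = proj[lo:hi]
        if w.sum() > 0:
            refined.append(lo + float((w * np.arange(w.size)).sum() / w.sum()))
    peaks = np.array(refined, dtype=float)
    if peaks.size < min_peaks:
        raise ValueError("no_grid_detected: too few projection peaks")
    spacing = float(np.median(np.diff(peaks))) if peaks.size >= 2 else spacing0
    # assign integer grid indices and refit origin + spacing by least squares
    idx = np.round((peaks - peaks[0]) / spacing).astype(int)
    idx -= idx.min()
    a = np.vstack([idx, np.ones_like(idx)]).T.astype(float)
    slope, intercept = np.linalg.lstsq(a, peaks, rcond=None)[0]
    # register the fitted axis within the image: indices of detected peaks
    # may not start at grid line 0 if leading lines were missed; choose the
    # shift whose candidate centers capture the most projection mass
    max_idx = idx.max()
    if max_idx >= n_expected:
        raise ValueError("no_grid_detected: projections inconsistent with grid size")
    best = None
    for shift in range(max_idx - (n_expected - 1), 1):
        cand = intercept + slope * (np.arange(n_expected) + shift)
        if cand[0] < -slope / 2 or cand[-1] > proj.size - 1 + slope / 2:
            continue
        pos = np.clip(np.round(cand).astype(int), 0, proj.size - 1)
        inside = (cand >= 0) & (cand <= proj.size - 1)
        score = float(smooth[pos][inside].sum())
        if best is None or score > best[0]:
            best = (score, cand)
    if best is None:
        raise ValueError("no_grid_detected: no registration fits the image")
    return best[1]


def detect_grid(
    image: PlateImage,
    rows: int = GRID_ROWS,
    cols: int = GRID_COLS,
    min_peaks: int = 8,
) -> GridSpec:
    """Locate the equidistant colony grid of a cropped plate image.

    Raises ``ValueError("no_grid_detected")`` when fewer than ``min_peaks``
    projection peaks are found on either axis.
    """
    mask = _foreground_mask(image.pixels)
    if not mask.any():
        raise ValueError("no_grid_detected: blank mask")
    centers_y = _axis_centers(mask.sum(axis=1).astype(float), rows, min_peaks)
    centers_x = _axis_centers(mask.sum(axis=0).astype(float), cols, min_peaks)
    return GridSpec(
        rows=rows,
        cols=cols,
        centers_y=centers_y,
        centers_x=centers_x,
        spacing_y=float(np.mean(np.diff(centers_y))),
        spacing_x=float(np.mean(np.diff(centers_x))),
    )


def _cell_bounds(grid: GridSpec, r: int, c: int, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    cy, cx = grid.center(r, c)
    hy, hx = grid.spacing_y / 2, grid.spacing_x / 2
    y0 = int(max(0, round(cy - hy)))
    y1 = int(min(shape[0], round(cy + hy)))
    x0 = int(max(0, round(cx - hx)))
    x1 = int(min(shape[1], round(cx + hx)))
    return y0, y1, x0, x1


def segment(
    image: PlateImage,
    grid: GridSpec,
    min_area: int = 5,
    min_contrast: float = 0.06,
) -> np.ndarray:
    """Per-cell colony segmentation: local Otsu threshold, largest
    connected component, hole filling.

    Returns an int32 label mask; grid position (r, c) has label
    ``r * cols + c + 1``, empty cells contribute no pixels. A cell counts
    as empty when its patch is nearly constant or when the foreground /
    background mean contrast stays below ``min_contrast`` (an Otsu split of
    pure pixel noise, not a colony).
    """
    pixels = image.pixels
    labels = np.zeros(pixels.shape, dtype=np.int32)
    for r in range(grid.rows):
        for c in range(grid.cols):
            y0, y1, x0, x1 = _cell_bounds(grid, r, c, pixels.shape)
            patch = pixels[y0:y1, x0:x1]
            if patch.size == 0 or patch.max() - patch.min() < 0.02:
                continue
            thr = threshold_otsu(patch)
            mask = patch > thr
            if not mask.any():
                continue
            comp, n = ndimage.label(mask)
            if n > 1:
                sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
                mask = comp == (1 + int(np.argmax(sizes)))
            mask = ndimage.binary_fill_holes(mask)
            if mask.sum() < min_area:
                continue
            if float(patch[mask].mean()) - float(patch[~mask].mean()) < min_contrast:
                continue
            labels[y0:y1, x0:x1][mask] = r * grid.cols + c + 1
    return labels


def measure(image: PlateImage, labels: np.ndarray, grid: GridSpec) -> list[ColonyMeasurement]:
    """Measure every grid position's colony area and mean foreground intensity.

    Area is the foreground pixel count of the cell's label. Intensity is
    the mean foreground pixel intensity after background removal: the mean
    level of the cell's background pixels is subtracted, so a smooth plate
    gradient does not leak into colony intensities. Positions without
    foreground are flagged ``missing``; colonies touching their cell
    boundary are flagged ``touching``.
    """
    pixels = image.pixels
    out: list[ColonyMeasurement] = []
    flat_labels = labels.ravel()
    flat_pixels = pixels.ravel()
    order = np.argsort(flat_labels, kind="stable")
    sorted_labels = flat_labels[order]
    boundaries = np.searchsorted(sorted_labels, np.arange(1, grid.rows * grid.cols + 2))
    for r in range(grid.rows):
        for c in range(grid.cols):
            lab = r * grid.cols + c + 1
            lo, hi = boundaries[lab - 1], boundaries[lab]
            area = int(hi - lo)
            if area == 0:
                out.append(ColonyMeasurement(r, c, 0, float("nan"), "missing"))
                continue
            vals = flat_pixels[order[lo:hi]]
            flag = ""
            y0, y1, x0, x1 = _cell_bounds(grid, r, c, pixels.shape)
            cell = labels[y0:y1, x0:x1] == lab
            patch = pixels[y0:y1, x0:x1]
            bg = patch[~cell]
            intensity = float(vals.mean()) - (float(bg.mean()) if bg.size else 0.0)
            # touching a neighboring cell is suspicious; touching the image
            # border merely means the crop clipped an outer cell
            if (
                (cell[0, :].any() and y0 > 0)
                or (cell[-1, :].any() and y1 < pixels.shape[0])
                or (cell[:, 0].any() and x0 > 0)
                or (cell[:, -1].any() and x1 < pixels.shape[1])
            ):
                flag = "touching"
            out.append(ColonyMeasurement(r, c, area, intensity, flag))
    return out


def measure_plate(
    raw: np.ndarray,
    layout: pd.DataFrame,
    invert: bool = False,
    crop_threshold: float = DEFAULT_CROP_THRESHOLD,
) -> pd.DataFrame:
    """Run the full image stage on one plate and join the strain layout.

    ``layout`` maps grid positions to strains: columns ``row``, ``col``,
    ``strain``, ``strain_class``. Returns one row per laid-out position
    with ``area``, ``intensity``, ``flag``.
    """
    img = preprocess(raw, invert=invert)
    cropped, _ = crop_plate(img, threshold=crop_threshold)
    grid = detect_grid(cropped)
    labels = segment(cropped, grid)
    measurements = measure(cropped, labels, grid)
    mdf = pd.DataFrame(
        [(m.row, m.col, m.area, m.intensity, m.flag) for m in measurements],
        columns=["row", "col", "area", "intensity", "flag"],
    )
    return layout.merge(mdf, on=["row", "col"], how="left")
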