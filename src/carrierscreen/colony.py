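"""Quantification of colony growth on robot-spotted agar plate images.

The algorithm works directly on the photograph of a plate:

1. take the blue channel of the RGB image;
2. from the four manually identified grid corners compute a *window size* —
   the larger of grid width / n_cols and grid length / n_rows;
3. partition the grid into equal diamond-shaped windows (L1 balls whose
   diagonals equal the window size), one framing each colony;
4. within each window, count the pixels whose intensity exceeds 1.25x the
   window minimum; that count is the colony size.

The threshold is *relative to the window minimum*, which makes the count
invariant to uniform illumination scaling of a window; the diamond shape
packs the square spot lattice without overlap between neighbouring windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import FormatError, GeometryError, LayoutError
from .catalog import PlateLayout

logger = logging.getLogger(__name__)

#: Relative intensity factor over the window minimum for a pixel to count
#: as colony. Strictly greater-than, so a uniform window always scores 0.
THRESHOLD_FACTOR = 1.25

#: Absolute tolerance on the L1 membership test (sub-pixel centre rounding).
MEMBERSHIP_EPS = 1e-9

Corners = tuple[
    tuple[float, float], tuple[float, float], tuple[float, float], tuple[float, float]
]


@dataclass(frozen=True)
class PlateImage:
    """A plate photograph plus the manually identified grid corners.

    ``pixels`` is H x W x 3 (RGB) or H x W (greyscale); ``corners`` are the
    (x, y) pixel coordinates of the spot-grid extent in the order top-left,
    top-right, bottom-left, bottom-right (x rightward, y downward).
    """

    pixels: np.ndarray
    corners: Corners


@dataclass(frozen=True)
class DiamondWindow:
    """One diamond-shaped analysis window framing a single colony.

    A pixel whose centre is (x + 0.5, y + 0.5) belongs to the window iff
    its L1 distance to ``center`` is at most ``half_diagonal``.
    """

    center: tuple[float, float]
    half_diagonal: float
    grid_index: tuple[int, int]

    def member_mask(self, height: int, width: int) -> tuple[np.ndarray, slice, slice]:
        """Boolean membership mask over the window's clipped bounding box.

        Returns (mask, row_slice, col_slice) so callers can index the image
        without materialising a full-frame mask.
        """
        cx, cy = self.center
        h = self.half_diagonal
        x0 = max(int(np.floor(cx - h)), 0)
        x1 = min(int(np.ceil(cx + h)) + 1, width)
        y0 = max(int(np.floor(cy - h)), 0)
        y1 = min(int(np.ceil(cy + h)) + 1, height)
        if x0 >= x1 or y0 >= y1:
            return np.zeros((0, 0), dtype=bool), slice(0, 0), slice(0, 0)
        xs = np.arange(x0, x1) + 0.5
        ys = np.arange(y0, y1) + 0.5
        # small tolerance so boundary pixels are classified consistently
        # under integer translations of the grid (bilinear centre rounding)
        mask = np.abs(xs[None, :] - cx) + np.abs(ys[:, None] - cy) <= h + MEMBERSHIP_EPS
        return mask, slice(y0, y1), slice(x0, x1)


def blue_channel(image: PlateImage | np.ndarray) -> np.ndarray:
    """Extract the blue channel used for colony sizing.

    Greyscale input passes through unchanged (with a log note); RGBA input
    drops alpha; any other channel count is a format error.
    """
    pixels = image.pixels if isinstance(image, PlateImage) else image
    if pixels.ndim == 2:
        logger.info("single-channel image: using it directly as the blue channel")
        return np.asarray(pixels)
    if pixels.ndim == 3 and pixels.shape[2] in (3, 4):
        return np.asarray(pixels[:, :, 2])
    raise FormatError(f"expected greyscale, RGB or RGBA image, got shape {pixels.shape}")


def _edge_lengths(corners: Corners) -> tuple[float, float]:
    (tlx, tly), (trx, try_), (blx, bly), (brx, bry) = corners
    width = 0.5 * (np.hypot(trx - tlx, try_ - tly) + np.hypot(brx - blx, bry - bly))
    length = 0.5 * (np.hypot(blx - tlx, bly - tly) + np.hypot(brx - trx, bry - try_))
    return float(width), float(length)


def window_size(corners: Corners, n_rows: int, n_cols: int) -> float:
    """Window size: max(grid width / n_cols, grid length / n_rows), unrounded."""
    if n_rows < 1 or n_cols < 1:
        raise GeometryError("grid must have at least one row and one column")
    width, length = _edge_lengths(corners)
    if width <= 0 or length <= 0:
        raise GeometryError(f"degenerate corners: width={width}, length={length}")
    return max(width / n_cols, length / n_rows)


def grid_centers(corners: Corners, n_rows: int, n_cols: int) -> np.ndarray:
    """Sub-pixel window centres on the bilinear lattice between the corners.

    Returns an (n_rows, n_cols, 2) array of (x, y); cell (i, j) sits at the
    fractional position ((j+0.5)/n_cols, (i+0.5)/n_rows) of the corner quad.
    """
    tl, tr, bl, br = (np.asarray(c, dtype=float) for c in corners)
    u = (np.arange(n_cols) + 0.5) / n_cols
    v = (np.arange(n_rows) + 0.5) / n_rows
    uu, vv = np.meshgrid(u, v)
    pts = (
        (1 - uu)[..., None] * (1 - vv)[..., None] * tl
        + uu[..., None] * (1 - vv)[..., None] * tr
        + (1 - uu)[..., None] * vv[..., None] * bl
        + uu[..., None] * vv[..., None] * br
    )
    return pts


def partition(image: PlateImage, n_rows: int, n_cols: int) -> list[DiamondWindow]:
    """Partition the corner-bounded grid into n_rows x n_cols diamond windows."""
    size = window_size(image.corners, n_rows, n_cols)
    half = size / 2.0
    if half <= 0:
        raise GeometryError("window size must be positive")
    height, width = blue_channel(image).shape
    centers = grid_centers(image.corners, n_rows, n_cols)
    windows = []
    clipped = 0
    for i in range(n_rows):
        for j in range(n_cols):
            cx, cy = centers[i, j]
            eps = 1e-6
            if cx - half < -eps or cy - half < -eps or cx + half > width + eps or cy + half > height + eps:
                clipped += 1
            windows.append(DiamondWindow((float(cx), float(cy)), half, (i, j)))
    if clipped:
        logger.warning("%d windows extend outside the image and were clipped", clipped)
    return windows


def colony_size(window: DiamondWindow, blue: np.ndarray) -> tuple[int, float]:
    """Count colony pixels in one window: intensity > 1.25 x window minimum.

    Returns ``(pixel_count, window_min)``; an empty window (fully clipped
    off the image) yields ``(-1, nan)`` and is flagged missing upstream.
    """
    height, width = blue.shape
    mask, ys, xs = window.member_mask(height, width)
    if not mask.any():
        return -1, float("nan")
    values = np.asarray(blue[ys, xs], dtype=float)[mask]
    wmin = float(values.min())
    count = int((values > THRESHOLD_FACTOR * wmin).sum())
    return count, wmin


def quantify_plate(image: PlateImage, layout: PlateLayout) -> pd.DataFrame:
    """Measure every spot of a plate and join strain identities.

    Returns one row per layout position: ``row``, ``col``, ``strain_id``,
    ``replicate_index``, ``is_edge``, ``pixel_count``, ``window_min``.
    Fully clipped windows get ``pixel_count = NaN`` (measurement missing).
    """
    windows = partition(image, layout.n_rows, layout.n_cols)
    blue = np.asarray(blue_channel(image), dtype=float)
    counts = np.empty(len(windows))
    mins = np.empty(len(windows))
    for k, win in enumerate(windows):
        count, wmin = colony_size(win, blue)
        counts[k] = np.nan if count < 0 else count
        mins[k] = wmin
    grid = pd.DataFrame(
        {
            "row": [w.grid_index[0] for w in windows],
            "col": [w.grid_index[1] for w in windows],
            "pixel_count": counts,
            "window_min": mins,
        }
    )
    merged = layout.frame.merge(grid, on=["row", "col"], how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        raise LayoutError("layout grid does not match the partition grid")
    merged = merged.drop(columns="_merge").sort_values(["row", "col"]).reset_index(drop=True)
    return merged[
        ["row", "col", "strain_id", "replicate_index", "is_edge", "pixel_count", "window_min"]
    ]


def load_image(path: str, corners: Corners) -> PlateImage:
    """Load a PNG/JPEG plate photograph from disk with its grid corners."""
    from PIL import Image

    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"))
    return PlateImage(arr, corners)
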