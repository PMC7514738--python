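"""Sliding-tile scanning and endoscopy-style image preprocessing.

A square tile slides pixel by pixel along a row or column of an image;
each tile is normalized independently and summarised by one entropy
point, so a scan yields a curve on the ``Sstr(ln q)`` map indexed by
the tile-center position.  Across a polyp this path forms hooks and
loops; across bowel-wall waves it is periodic.

The preprocessing chain for real frames is: specular-reflection
removal, histogram stretching, and subtraction of a large-scale
box-mean background (which removes tilts and slow illumination
gradients).  Each step is recorded in a metadata dictionary so runs
are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .entropy import EntropyPoint, entropy_point

__all__ = [
    "TileSpec",
    "ScanCurve",
    "load_image",
    "split_channels",
    "remove_offset",
    "mean_filter_background",
    "subtract_background",
    "stretch_histogram",
    "remove_reflections",
    "preprocess",
    "slide_scan",
    "fixed_tiling",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TileSpec:
    """Sliding-tile geometry.

    ``axis="row"`` scans along a row (tile centers moving across
    columns at the given ``line_index`` row); ``axis="column"`` scans
    down a column.  Only positions where the full tile fits inside the
    image are used, so a scan is shorter than the image line by
    ``tile_size - 1`` pixels.
    """

    tile_size: int = 50
    stride: int = 1
    axis: str = "row"
    line_index: int | None = None

    def __post_init__(self):
        if self.tile_size < 2:
            raise ValueError("tile_size must be at least 2")
        if self.stride < 1:
            raise ValueError("stride must be at least 1")
        if self.axis not in ("row", "column"):
            raise ValueError("axis must be 'row' or 'column'")


@dataclass
class ScanCurve:
    """Entropy points of a sliding-tile scan along one image line."""

    positions: np.ndarray
    points: list[EntropyPoint]
    tile_spec: TileSpec
    channel: str = ""
    excluded: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def s_str(self) -> np.ndarray:
        return np.array([pt.s_str for pt in self.points])

    @property
    def ln_q(self) -> np.ndarray:
        return np.array([pt.ln_q for pt in self.points])

    def path(self) -> np.ndarray:
        """The ``(ln q, Sstr)`` path of the scan."""
        return np.column_stack([self.ln_q, self.s_str])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pos, pt in zip(self.positions, self.points):
            row = {"channel": self.channel, "position": pos}
            row.update(pt.as_dict())
            row["flags"] = ""
            rows.append(row)
        for pos in self.excluded:
            rows.append({"channel": self.channel, "position": pos, "flags": "degenerate"})
        frame = pd.DataFrame(rows)
        return frame.sort_values("position", kind="stable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def load_image(path) -> np.ndarray:
    """Read an 8- or 16-bit PNG/TIFF image as an array."""
    image = iio.imread(path)
    return np.asarray(image)


def split_channels(image) -> dict[str, np.ndarray]:
    """Split an image array into named float intensity grids.

    Grayscale input yields ``{"gray": grid}``; RGB(A) input yields the
    ``"R"``, ``"G"``, ``"B"`` channels (alpha dropped) — the channels
    emphasise different anatomy, so they are analysed independently.
    Integer values are preserved exactly as floats.  An all-black
    channel is flagged degenerate and excluded.
    """
    arr = np.asarray(image)
    if arr.dtype not in (np.uint8, np.uint16) and not np.issubdtype(
        arr.dtype, np.floating
    ):
        raise ValueError("unsupported bit depth: %s (need 8/16-bit or float)" % arr.dtype)
    if arr.ndim == 2:
        named = {"gray": arr.astype(float)}
    elif arr.ndim == 3 and arr.shape[2] in (3, 4):
        named = {
            name: arr[:, :, i].astype(float) for i, name in enumerate("RGB")
        }
    else:
        raise ValueError("expected a 2-D grayscale or 3-channel image, got shape %s"
                         % (arr.shape,))
    out = {}
    for name, grid in named.items():
        if not np.any(grid > 0):
            logger.warning("channel %s is all-black; excluded as degenerate", name)
            continue
        out[name] = grid
    return out


def remove_offset(grid) -> np.ndarray:
    """Counter-offset: shift intensities so the minimum is exactly 0."""
    grid = np.asarray(grid, dtype=float)
    return grid - grid.min()


def mean_filter_background(grid, size: int) -> np.ndarray:
    """``size x size`` box-mean of the image with reflect padding.

    A sufficiently large filter estimates the slow background
    (illumination, tilt) while averaging out structures smaller than
    the filter.
    """
    grid = np.asarray(grid, dtype=float)
    if size < 1:
        raise ValueError("filter size must be at least 1")
    if size > max(grid.shape):
        raise ValueError(
            "filter size %d exceeds both image dimensions %s" % (size, grid.shape)
        )
    return ndimage.uniform_filter(grid, size=size, mode="reflect")


def subtract_background(grid, size: int) -> np.ndarray:
    """Remove the box-mean background and shift the result to >= 0.

    Removes tilts and large-scale shading; structures on scales well
    below the filter size survive.  Note the filter size matters: one
    comparable to a polyp diameter suppresses the polyp itself, one
    about twice the diameter keeps it.
    """
    grid = np.asarray(grid, dtype=float)
    residual = grid - mean_filter_background(grid, size)
    return residual - residual.min()


def stretch_histogram(grid, out_max: float = 255.0) -> np.ndarray:
    """Linear map of the intensity range onto ``[0, out_max]``.

    Affine stretching is not a pure rescaling, so it changes entropy
    points whenever the input minimum is positive.  Idempotent on
    already-stretched input.  A constant grid cannot be stretched.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = float(grid.min()), float(grid.max())
    if hi == lo:
        raise ValueError("cannot stretch a constant grid")
    if out_max <= 0:
        raise ValueError("out_max must be positive")
    return (grid - lo) * (out_max / (hi - lo))


def remove_reflections(
    grid,
    saturation_fraction: float = 0.95,
    neighborhood: int = 5,
    range_max: float | None = None,
):
    """Replace saturated (specular-glare) pixels by a local mean.

    Pixels at or above ``saturation_fraction * range_max`` (default
    ``range_max`` is the grid maximum) are treated as reflections and
    replaced by the mean of the non-saturated pixels in a surrounding
    square neighborhood, grown until it contains at least 8 valid
    pixels.

    Returns
    -------
    (numpy.ndarray, numpy.ndarray)
        The cleaned grid and the boolean mask of replaced pixels.

    Raises
    ------
    ValueError
        If more than half of the frame is saturated ("unusable frame").
    """
    grid = np.asarray(grid, dtype=float)
    if not 0 < saturation_fraction <= 1:
        raise ValueError("saturation_fraction must be in (0, 1]")
    if range_max is None:
        range_max = float(grid.max())
    threshold = saturation_fraction * range_max
    mask = grid >= threshold
    if not mask.any():
        return grid.copy(), mask
    if mask.mean() > 0.5:
        raise ValueError("unusable frame: more than 50%% saturated "
                         "(%.1f%%)" % (100 * mask.mean()))
    cleaned = grid.copy()
    n_rows, n_cols = grid.shape
    for i, j in zip(*np.nonzero(mask)):
        half = max(neighborhood // 2, 1)
        while True:
            r0, r1 = max(i - half, 0), min(i + half + 1, n_rows)
            c0, c1 = max(j - half, 0), min(j + half + 1, n_cols)
            window = grid[r0:r1, c0:c1]
            valid = window[~mask[r0:r1, c0:c1]]
            if valid.size >= 8 or (r1 - r0 == n_rows and c1 - c0 == n_cols):
                break
            half *= 2
        cleaned[i, j] = valid.mean() if valid.size else threshold
    return cleaned, mask


def preprocess(
    grid,
    saturation_fraction: float = 0.95,
    out_max: float = 255.0,
    background_size: int = 200,
    range_max: float | None = None,
):
    """Full preprocessing chain for a single channel.

    Order: reflection removal -> histogram stretching -> mean-filtered
    background subtraction.  Returns the processed grid and a metadata
    dictionary recording the steps, their parameters and the number of
    replaced pixels.
    """
    cleaned, mask = remove_reflections(
        grid, saturation_fraction=saturation_fraction, range_max=range_max
    )
    stretched = stretch_histogram(cleaned, out_max=out_max)
    flattened = subtract_background(stretched, background_size)
    metadata = {
        "steps": ["remove_reflections", "stretch_histogram", "subtract_background"],
        "saturation_fraction": saturation_fraction,
        "saturated_pixels": int(mask.sum()),
        "out_max": out_max,
        "background_size": background_size,
    }
    return flattened, metadata


def _line_window(grid: np.ndarray, spec: TileSpec):
    """Resolve scan geometry: returns (line0, length, extract)."""
    n_rows, n_cols = grid.shape
    if spec.axis == "row":
        line = n_rows // 2 if spec.line_index is None else spec.line_index
        if not 0 <= line < n_rows:
            raise ValueError("line_index %d outside image rows" % line)
        length = n_cols
    else:
        line = n_cols // 2 if spec.line_index is None else spec.line_index
        if not 0 <= line < n_cols:
            raise ValueError("line_index %d outside image columns" % line)
        length = n_rows
    # top/left edge of the tile across the scan line, clipped to fit
    perp0 = min(max(line - spec.tile_size // 2, 0),
                (n_rows if spec.axis == "row" else n_cols) - spec.tile_size)
    if perp0 < 0:
        raise ValueError("tile larger than image")

    def extract(start: int) -> np.ndarray:
        if spec.axis == "row":
            return grid[perp0 : perp0 + spec.tile_size, start : start + spec.tile_size]
        return grid[start : start + spec.tile_size, perp0 : perp0 + spec.tile_size]

    return length, extract


def slide_scan(grid, spec: TileSpec | None = None, floor_offset: float = 0.0) -> ScanCurve:
    """Scan an image line with a sliding tile.

    For every position where the full tile fits
    (``floor((L - tile)/stride) + 1`` positions along the scanned
    line), the tile is extracted, normalized independently and reduced
    to one entropy point.  Positions are reported as tile-center
    coordinates, ``start + (tile_size - 1) / 2``.  Tiles that are
    all-zero are flagged degenerate, logged and excluded.
    """
    grid = np.asarray(grid, dtype=float)
    spec = spec or TileSpec()
    if spec.tile_size > min(grid.shape):
        raise ValueError(
            "tile size %d does not fit in image %s" % (spec.tile_size, grid.shape)
        )
    length, extract = _line_window(grid, spec)
    positions, points, excluded = [], [], []
    for start in range(0, length - spec.tile_size + 1, spec.stride):
        center = start + (spec.tile_size - 1) / 2.0
        tile = extract(start)
        try:
            points.append(entropy_point(tile, floor_offset=floor_offset))
            positions.append(center)
        except ValueError:
            logger.warning("degenerate (all-zero) tile at position %.1f; excluded",
                           center)
            excluded.append(center)
    return ScanCurve(
        positions=np.asarray(positions, dtype=float),
        points=points,
        tile_spec=spec,
        excluded=excluded,
    )


def fixed_tiling(grid, tile_size: int, floor_offset: float = 0.0):
    """Non-overlapping tiling from the top-left corner.

    Partial edge tiles are dropped; each full tile is normalized and
    summarised independently.  Returns a list of
    ``((row0, col0), EntropyPoint)`` pairs; degenerate (all-zero) tiles
    are excluded with a log message.
    """
    grid = np.asarray(grid, dtype=float)
    if tile_size < 2:
        raise ValueError("tile_size must be at least 2")
    n_rows, n_cols = grid.shape
    if tile_size > n_rows or tile_size > n_cols:
        raise ValueError("tile size %d exceeds image dimensions %s"
                         % (tile_size, grid.shape))
    out = []
    for r0 in range(0, n_rows - tile_size + 1, tile_size):
        for c0 in range(0, n_cols - tile_size + 1, tile_size):
            tile = grid[r0 : r0 + tile_size, c0 : c0 + tile_size]
            try:
                out.append(((r0, c0), entropy_point(tile, floor_offset=floor_offset)))
            except ValueError:
                logger.warning("degenerate tile at (%d, %d); excluded", r0, c0)
    return out
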