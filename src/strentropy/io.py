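"""Serialization of grids and curves: PNG/TIFF, CSV and sidecar JSON.

Model surfaces are real-valued; writing them as 16-bit images requires
a linear scaling, which is recorded in a sidecar JSON so the grid can
be recovered (and so fixtures are reproducible).  Curves go to CSV with
12 significant digits, enough for derived columns to recompute to 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["write_grid_image", "read_grid_image", "write_grid_csv", "read_grid_csv",
           "write_provenance"]

FLOAT_FORMAT = "%.12g"


def write_grid_image(grid, path, bit_depth: int = 16) -> dict:
    """Write a grid as an 8/16-bit grayscale PNG/TIFF plus sidecar JSON.

    The grid is linearly mapped onto the full integer range; the map
    ``value = scale * pixel + offset`` is stored in ``<path>.json``.
    Returns the sidecar dictionary.
    """
    grid = np.asarray(grid, dtype=float)
    if bit_depth == 16:
        dtype, vmax = np.uint16, 65535
    elif bit_depth == 8:
        dtype, vmax = np.uint8, 255
    else:
        raise ValueError("bit_depth must be 8 or 16")
    lo, hi = float(grid.min()), float(grid.max())
    scale = (hi - lo) / vmax if hi > lo else 1.0
    pixels = np.round((grid - lo) / scale).astype(dtype) if hi > lo else np.zeros(
        grid.shape, dtype=dtype
    )
    path = Path(path)
    iio.imwrite(path, pixels)
    sidecar = {"scale": scale, "offset": lo, "bit_depth": bit_depth,
               "shape": list(grid.shape)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return sidecar


def read_grid_image(path) -> np.ndarray:
    """Read a grid image written by :func:`write_grid_image`.

    Applies the sidecar scaling if present, otherwise returns raw pixel
    values as floats.
    """
    path = Path(path)
    pixels = np.asarray(iio.imread(path), dtype=float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        return pixels * sidecar["scale"] + sidecar["offset"]
    return pixels


def write_grid_csv(grid, path) -> None:
    """Write a grid as a plain CSV matrix."""
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",", fmt=FLOAT_FORMAT)


def read_grid_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_provenance(path, config: dict) -> None:
    """Write a machine-readable provenance block next to an output."""
    import hashlib

    from . import __version__

    body = json.dumps(config, sort_keys=True, default=str)
    record = {
        "strentropy_version": __version__,
        "numpy_version": np.__version__,
        "config": config,
        "config_sha256": hashlib.sha256(body.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(record, indent=1, default=str))
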