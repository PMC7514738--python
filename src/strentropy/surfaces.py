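"""Synthetic model surfaces for bowel-wall and polyp intensity patterns.

The elementary structures visible on colonoscopy frames are waves
(folds of the bowel wall, straight or concentric in perspective),
hemisphere/half-ellipsoid bumps (polyps) and the shadow valleys around
them.  This module generates those structures as deterministic
non-negative intensity fields on pixel grids, in the configurations a
scanning analysis needs: plane or cone tilts imitating the darkening of
distant bowel regions, and additive or multiplicative superpositions.

Coordinates are centered: ``x = col - (n_cols - 1) / 2`` and
``y = row - (n_rows - 1) / 2``, so ``(0, 0)`` is the tile center (exact
pixel for odd sizes).  Phases are specified in degrees.  Every generator
is deterministic: identical parameters give bit-identical grids.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = [
    "centered_coordinates",
    "straight_wave",
    "circular_wave",
    "apply_tilt",
    "half_ellipsoid",
    "exponential_shadow",
    "polyp_model",
    "superpose_additive",
    "superpose_multiplicative",
]

logger = logging.getLogger(__name__)

_NONNEG_TOL = 1e-12


def _shape(shape) -> tuple[int, int]:
    if np.isscalar(shape):
        n = int(shape)
        if n < 2:
            raise ValueError("grid side must be at least 2 pixels")
        return (n, n)
    n_rows, n_cols = (int(s) for s in shape)
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid sides must be at least 2 pixels")
    return (n_rows, n_cols)


def centered_coordinates(shape):
    """Return centered coordinate grids ``(x, y)`` for a grid shape.

    ``shape`` may be a single side length ``N`` (square tile) or a
    ``(n_rows, n_cols)`` pair.  ``x`` runs along columns, ``y`` along
    rows, both zero at the tile center.
    """
    n_rows, n_cols = _shape(shape)
    x = np.arange(n_cols, dtype=float) - (n_cols - 1) / 2.0
    y = np.arange(n_rows, dtype=float) - (n_rows - 1) / 2.0
    return np.meshgrid(x, y)


def _check_wave_amplitude(amplitude: float, offset: float) -> None:
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if amplitude > 0.5 + offset + _NONNEG_TOL:
        raise ValueError(
            "amplitude %g would push the wave below zero (max 0.5 + offset)"
            % amplitude
        )


def straight_wave(
    shape,
    wavelength_x: float = np.inf,
    wavelength_y: float = np.inf,
    phase_deg: float = 0.0,
    offset: float = 0.0,
    amplitude: float = 0.5,
) -> np.ndarray:
    """Sinusoidal wave with a straight wavefront.

    ``f(x, y) = amplitude * sin(2 pi x / Tx + 2 pi y / Ty + phi) + 0.5
    + offset``.  Either wavelength may be infinite (no variation along
    that axis); with the default amplitude 0.5 the range is
    ``[offset, 1 + offset]``, keeping the field non-negative.  The
    wavefront direction is set by the ratio of the two wavelength
    components.
    """
    if wavelength_x == 0 or wavelength_y == 0:
        raise ValueError("wavelength components must be non-zero")
    _check_wave_amplitude(amplitude, offset)
    x, y = centered_coordinates(shape)
    arg = np.deg2rad(phase_deg) + 2 * np.pi * (
        (x / wavelength_x if np.isfinite(wavelength_x) else 0.0)
        + (y / wavelength_y if np.isfinite(wavelength_y) else 0.0)
    )
    if np.isscalar(arg):  # both wavelengths infinite
        arg = np.full_like(x, arg)
    return amplitude * np.sin(arg) + 0.5 + offset


def circular_wave(
    shape,
    wavelength_x: float,
    wavelength_y: float | None = None,
    center_x: float = 0.0,
    center_y: float = 0.0,
    phase_deg: float = 0.0,
    offset: float = 0.0,
    amplitude: float = 0.5,
) -> np.ndarray:
    """Sinusoidal wave with concentric (circular or elliptic) fronts.

    ``f = amplitude * sin( sqrt[(2 pi (x-x0)/Tx)^2 + (2 pi (y-y0)/Ty)^2]
    + phi ) + 0.5 + offset``.  With ``Tx = Ty`` the fronts are circles
    around ``(x0, y0)`` (tile-centered coordinates); a center far
    outside the tile makes the fronts locally straight, which is the
    realistic configuration for bowel folds seen in perspective.
    """
    if wavelength_y is None:
        wavelength_y = wavelength_x
    if wavelength_x <= 0 or wavelength_y <= 0:
        raise ValueError("wavelengths must be positive")
    _check_wave_amplitude(amplitude, offset)
    x, y = centered_coordinates(shape)
    radial = np.sqrt(
        (2 * np.pi * (x - center_x) / wavelength_x) ** 2
        + (2 * np.pi * (y - center_y) / wavelength_y) ** 2
    )
    return amplitude * np.sin(radial + np.deg2rad(phase_deg)) + 0.5 + offset


def apply_tilt(
    grid,
    slope: float,
    kind: str = "plane",
    direction=(1.0, 0.0),
    center=(0.0, 0.0),
) -> np.ndarray:
    """Add an intensity ramp imitating darkening toward distant regions.

    ``kind="plane"`` adds ``slope`` times the signed distance along
    ``direction`` (a 2-vector in ``(x, y)``), shifted so the added ramp
    is everywhere >= 0 — the tilt used with straight wavefronts,
    normally perpendicular to the fronts.  ``kind="cone"`` adds
    ``slope`` times the radial distance from ``center`` — the conical
    tilt used with circular fronts, apex at the wave center.  A slope of
    0 returns the grid unchanged.
    """
    grid = np.asarray(grid, dtype=float)
    if slope < 0:
        raise ValueError("slope must be non-negative")
    if slope == 0:
        return grid.copy()
    x, y = centered_coordinates(grid.shape)
    if kind == "plane":
        dx, dy = (float(c) for c in direction)
        norm = np.hypot(dx, dy)
        if norm == 0:
            raise ValueError("tilt direction must be a non-zero vector")
        s = (x * dx + y * dy) / norm
        ramp = slope * (s - s.min())
    elif kind == "cone":
        cx, cy = (float(c) for c in center)
        ramp = slope * np.hypot(x - cx, y - cy)
        ramp -= ramp.min()
    else:
        raise ValueError("tilt kind must be 'plane' or 'cone'")
    return grid + ramp


def half_ellipsoid(
    shape,
    radius: float,
    axis_x: float = 1.0,
    axis_y: float = 1.0,
    center_x: float = 0.0,
    center_y: float = 0.0,
    background: float = 1e-10,
) -> np.ndarray:
    """Half ellipsoid (hemisphere for unit axis ratios) height field.

    ``f = max( sqrt(max(0, R^2 - ((x-rx)/Rx)^2 - ((y-ry)/Ry)^2)),
    background )``: peak value ``R`` at the center, elliptical footprint
    with semi-axes ``R*Rx`` and ``R*Ry``, flat ``background`` outside.
    This is the basic polyp model — a roundish bump on a dark floor.
    """
    if radius <= 0 or axis_x <= 0 or axis_y <= 0:
        raise ValueError("radius and axis distortions must be positive")
    if background < 0:
        raise ValueError("background must be non-negative")
    x, y = centered_coordinates(shape)
    h2 = radius**2 - ((x - center_x) / axis_x) ** 2 - ((y - center_y) / axis_y) ** 2
    return np.maximum(np.sqrt(np.clip(h2, 0.0, None)), background)


def exponential_shadow(
    shape,
    sigma_x: float,
    sigma_y: float | None = None,
    alpha: float = 2.0,
    center_x: float = 0.0,
    center_y: float = 0.0,
) -> np.ndarray:
    """Generalized-Gaussian valley profile with unit peak.

    ``f = exp(-rho^(alpha/2))`` with the elliptic radius
    ``rho = (x-rx)^2/sx^2 + (y-ry)^2/sy^2``; ``alpha = 2`` is exactly
    the Gaussian ``exp(-rho)``.  Larger ``alpha`` gives a wider, flatter
    central part and a quicker decrease — alternative models for the
    shadow ring around a polyp.  At the elliptic radius ``rho = 1`` the
    value is ``exp(-1)`` for every ``alpha``.
    """
    if sigma_y is None:
        sigma_y = sigma_x
    if sigma_x <= 0 or sigma_y <= 0:
        raise ValueError("shadow widths must be positive")
    if alpha < 1:
        raise ValueError("shape exponent alpha must be >= 1")
    x, y = centered_coordinates(shape)
    rho = ((x - center_x) / sigma_x) ** 2 + ((y - center_y) / sigma_y) ** 2
    return np.exp(-(rho ** (alpha / 2.0)))


def polyp_model(
    shape,
    radius: float,
    height: float,
    depth: float,
    offset: float = 0.0,
    alpha: float = 2.0,
    sigma: float | None = None,
    center_x: float = 0.0,
    center_y: float = 0.0,
    axis_x: float = 1.0,
    axis_y: float = 1.0,
    floor: float = 0.0,
) -> np.ndarray:
    """Polyp-with-shadow model: bump minus valley on a flat offset.

    ``f = offset + height * hemisphere(unit peak) - depth * shadow``,
    clamped from below at ``floor``.  The shadow is centered on the
    bump and its widths default to the bump radius (``sigma = R``),
    which reproduces the characteristic cross-section of a real polyp:
    a central bump flanked by two minima dipping below the offset
    level.  If the unclamped minimum dips below ``-offset`` the
    configuration is suspicious (a large clamped region) and a warning
    is logged before clamping.
    """
    if height < 0 or depth < 0 or offset < 0:
        raise ValueError("height, depth and offset must be non-negative")
    if sigma is None:
        sigma = radius
    bump = half_ellipsoid(
        shape,
        radius,
        axis_x=axis_x,
        axis_y=axis_y,
        center_x=center_x,
        center_y=center_y,
        background=0.0,
    ) / radius
    valley = exponential_shadow(
        shape,
        sigma_x=sigma * axis_x,
        sigma_y=sigma * axis_y,
        alpha=alpha,
        center_x=center_x,
        center_y=center_y,
    )
    surface = offset + height * bump - depth * valley
    unclamped_min = float(surface.min())
    if unclamped_min < -offset:
        logger.warning(
            "polyp model dips to %.3g (|min| > offset %.3g); clamping at %.3g",
            unclamped_min,
            offset,
            floor,
        )
    return np.clip(surface, floor, None)


def superpose_additive(a, b, weight_a: float = 1.0, weight_b: float = 1.0) -> np.ndarray:
    """Weighted sum of two surfaces, ``w_a * a + w_b * b``.

    In an additive superposition the component structures are only
    detectable on the entropy map when one of them dominates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch: %s vs %s" % (a.shape, b.shape))
    if weight_a < 0 or weight_b < 0:
        raise ValueError("weights must be non-negative")
    return weight_a * a + weight_b * b


def superpose_multiplicative(a, b) -> np.ndarray:
    """Elementwise product of two surfaces.

    For multiplicative superstructures the structural entropies and
    ``ln q`` values of the components add: in particular for
    outer-product (separable) fields the 2-D quantities equal the sums
    of the 1-D profile quantities exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch: %s vs %s" % (a.shape, b.shape))
    product = a * b
    if not np.any(product > 0):
        raise ValueError("degenerate distribution: product is identically zero")
    return product
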