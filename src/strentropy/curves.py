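"""Characteristic curves on the structural-entropy / filling-factor map.

A shape family (wave, hemisphere, shadow, Gaussian, ...) traces a curve
on the ``Sstr(ln q)`` plane as one of its parameters is swept; those
characteristic curves — not the individual points — are what
distinguishes structures.  This module provides:

* a parameter-sweep engine over the registered surface families,
* the reference curves of the radially symmetric 2-D Gaussian,
  exponential and second-order power-law densities, whose plateaus sit
  at the closed-form continuum constants ``1 - ln 2``, ``2 - ln 4`` and
  ``2 - ln 3``,
* the theoretical limit line ``Sstr = -ln q``,
* geometric features of a curve (turning points, loop closure, hook
  magnitudes) used for qualitative shape checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import surfaces
from .entropy import EntropyPoint, entropy_point

__all__ = [
    "CharacteristicCurve",
    "SURFACE_FAMILIES",
    "REFERENCE_CONSTANTS",
    "parameter_sweep",
    "reference_curve",
    "limit_line",
    "curve_features",
    "CurveFeatures",
    "plateau_value",
    "oscillation_amplitude",
    "peak_prominences",
]

# continuum structural-entropy plateau constants of the radially
# symmetric 2-D densities (from the closed-form integrals of p ln p
# and p^2):
#   gaussian     p ~ exp(-r^2/s^2)      -> 1 - ln 2
#   exponential  p ~ exp(-r/s)          -> 2 - ln 4
#   power_law_2  p ~ (1 + (r/s)^2)^-2   -> 2 - ln 3
REFERENCE_CONSTANTS = {
    "gaussian": 1.0 - np.log(2.0),
    "exponential": 2.0 - np.log(4.0),
    "power_law_2": 2.0 - np.log(3.0),
}


def _tilted_straight_wave(shape, tilt_ratio=np.inf, **params):
    """Straight wave plus a plane tilt perpendicular to the wavefront.

    ``tilt_ratio`` is the wavelength-to-gradient ratio; the added ramp
    has slope ``T / tilt_ratio`` per pixel (infinite ratio = no tilt).
    """
    grid = surfaces.straight_wave(shape, **params)
    if not np.isfinite(tilt_ratio):
        return grid
    tx = params.get("wavelength_x", np.inf)
    ty = params.get("wavelength_y", np.inf)
    wavelength = min(abs(t) for t in (tx, ty) if np.isfinite(t))
    direction = (
        1.0 / tx if np.isfinite(tx) else 0.0,
        1.0 / ty if np.isfinite(ty) else 0.0,
    )
    return surfaces.apply_tilt(
        grid, slope=wavelength / tilt_ratio, kind="plane", direction=direction
    )


def _tilted_circular_wave(shape, tilt_ratio=np.inf, **params):
    """Circular wave plus a conical tilt with apex at the wave center."""
    grid = surfaces.circular_wave(shape, **params)
    if not np.isfinite(tilt_ratio):
        return grid
    wavelength = min(
        params["wavelength_x"], params.get("wavelength_y") or params["wavelength_x"]
    )
    return surfaces.apply_tilt(
        grid,
        slope=wavelength / tilt_ratio,
        kind="cone",
        center=(params.get("center_x", 0.0), params.get("center_y", 0.0)),
    )


SURFACE_FAMILIES = {
    "straight_wave": surfaces.straight_wave,
    "circular_wave": surfaces.circular_wave,
    "straight_wave_tilted": _tilted_straight_wave,
    "circular_wave_tilted": _tilted_circular_wave,
    "half_ellipsoid": surfaces.half_ellipsoid,
    "exponential_shadow": surfaces.exponential_shadow,
    "polyp_model": surfaces.polyp_model,
}


@dataclass
class CharacteristicCurve:
    """Ordered entropy points of one family indexed by a swept parameter."""

    family: str
    param_name: str
    param_values: list
    points: list[EntropyPoint]
    fixed: dict = field(default_factory=dict)
    grid_shape: tuple | None = None
    warn_flags: list[bool] | None = None

    def __post_init__(self):
        if len(self.param_values) != len(self.points):
            raise ValueError("one entropy point per parameter value required")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def s_str(self) -> np.ndarray:
        return np.array([pt.s_str for pt in self.points])

    @property
    def ln_q(self) -> np.ndarray:
        return np.array([pt.ln_q for pt in self.points])

    def path(self) -> np.ndarray:
        """The ``(ln q, Sstr)`` path as an ``(n, 2)`` array."""
        return np.column_stack([self.ln_q, self.s_str])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (val, pt) in enumerate(zip(self.param_values, self.points)):
            row = {"family": self.family, self.param_name: val}
            row.update(pt.as_dict())
            if self.warn_flags is not None:
                row["warn"] = bool(self.warn_flags[i])
            rows.append(row)
        frame = pd.DataFrame(rows)
        for key, value in self.fixed.items():
            if np.isscalar(value):
                frame[key] = value
        return frame

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def parameter_sweep(
    family: str,
    param_name: str,
    param_values,
    secondary_name: str | None = None,
    secondary_values=None,
    fixed: dict | None = None,
    grid_shape=200,
    floor_offset: float = 0.0,
) -> list[CharacteristicCurve]:
    """Sweep one (or two) parameters of a surface family.

    For each value of the optional secondary parameter one
    ``CharacteristicCurve`` is produced, its points ordered along the
    primary parameter — one curve per color in the classic plot.
    Values of the primary parameter must be strictly ordered.  All
    remaining generator parameters are passed through ``fixed``.

    Generator errors propagate annotated with the offending parameter
    values.
    """
    if family not in SURFACE_FAMILIES:
        raise KeyError(
            "unknown family %r; choose from %s" % (family, sorted(SURFACE_FAMILIES))
        )
    values = list(param_values)
    if len(values) == 0:
        raise ValueError("primary parameter sweep is empty")
    diffs = np.diff(np.asarray(values, dtype=float))
    if len(values) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("primary parameter values must be strictly ordered")
    generator = SURFACE_FAMILIES[family]
    fixed = dict(fixed or {})
    secondary = [None] if secondary_name is None else list(secondary_values)

    curves = []
    for sec in secondary:
        params = dict(fixed)
        if secondary_name is not None:
            params[secondary_name] = sec
        points = []
        for val in values:
            params[param_name] = val
            try:
                grid = generator(grid_shape, **params)
                points.append(entropy_point(grid, floor_offset=floor_offset))
            except Exception as exc:
                raise type(exc)(
                    "%s [family=%s, %s=%r%s]"
                    % (
                        exc,
                        family,
                        param_name,
                        val,
                        "" if sec is None else ", %s=%r" % (secondary_name, sec),
                    )
                ) from exc
        meta = dict(fixed)
        if secondary_name is not None:
            meta[secondary_name] = sec
        curves.append(
            CharacteristicCurve(
                family=family,
                param_name=param_name,
                param_values=values,
                points=points,
                fixed=meta,
                grid_shape=surfaces._shape(grid_shape),
            )
        )
    return curves


def reference_curve(
    shape_family: str, scales, grid_size: int = 512
) -> CharacteristicCurve:
    """Reference curve of a radially symmetric 2-D density family.

    Evaluates the density on an ``N x N`` centered grid at each scale
    and computes the entropy point.  Within the discretization- and
    truncation-safe band ``[3, N/10]`` the structural entropies form a
    plateau at the family's continuum constant
    (:data:`REFERENCE_CONSTANTS`); points outside the band carry a
    warning flag.  Heavy-tailed families (the power law) additionally
    drift off the constant at the large-scale end of the band as the
    finite grid truncates their tails, so the plateau sits at the flat
    part of the curve (see :func:`plateau_value`).
    """
    if shape_family not in REFERENCE_CONSTANTS:
        raise KeyError(
            "unknown reference family %r; choose from %s"
            % (shape_family, sorted(REFERENCE_CONSTANTS))
        )
    x, y = surfaces.centered_coordinates(grid_size)
    r2 = x**2 + y**2
    scales = list(scales)
    lo, hi = 3.0, grid_size / 10.0
    points, warn = [], []
    for s in scales:
        if s <= 0:
            raise ValueError("scales must be positive")
        if shape_family == "gaussian":
            density = np.exp(-r2 / s**2)
        elif shape_family == "exponential":
            density = np.exp(-np.sqrt(r2) / s)
        else:  # power_law_2
            density = (1.0 + r2 / s**2) ** -2
        points.append(entropy_point(density))
        warn.append(not (lo <= s <= hi))
    return CharacteristicCurve(
        family=shape_family,
        param_name="scale",
        param_values=scales,
        points=points,
        fixed={"constant": REFERENCE_CONSTANTS[shape_family]},
        grid_shape=(grid_size, grid_size),
        warn_flags=warn,
    )


def limit_line(ln_q_values) -> np.ndarray:
    """The theoretical bound ``Sstr = -ln q`` as ``(ln q, Sstr)`` pairs.

    Every entropy point of every distribution lies on or below this
    line.
    """
    ln_q = np.asarray(ln_q_values, dtype=float)
    if np.any(ln_q > 0):
        raise ValueError("ln q must be non-positive")
    return np.column_stack([ln_q, -ln_q])


@dataclass(frozen=True)
class CurveFeatures:
    """Geometric summary of a path on the ``Sstr(ln q)`` plane."""

    n_turning_points: int
    loop_closed: bool
    extent_ln_q: float
    extent_s_str: float


def _moving_average(values: np.ndarray, window: int = 3) -> np.ndarray:
    if len(values) < window:
        return values
    kernel = np.ones(window) / window
    smoothed = values.copy()
    smoothed[window // 2 : -(window // 2)] = np.convolve(values, kernel, mode="valid")
    return smoothed


def curve_features(curve, closure_tol: float = 0.01, smooth_window: int = 3):
    """Turning points, loop closure and extents of an entropy-map path.

    ``curve`` is a :class:`CharacteristicCurve`, a scan curve, or a
    plain ``(n, 2)`` array of ``(ln q, Sstr)`` pairs (n >= 3).  Turning
    points are sign changes of the discrete curvature (z-component of
    the cross product of successive segments) after light smoothing; the
    loop is closed when the first and last points are within
    ``closure_tol`` times the path's diagonal extent.
    """
    path = curve.path() if hasattr(curve, "path") else np.asarray(curve, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) < 3:
        raise ValueError("need at least 3 (ln q, Sstr) points")
    sm = np.column_stack(
        [_moving_average(path[:, 0], smooth_window), _moving_average(path[:, 1], smooth_window)]
    )
    seg = np.diff(sm, axis=0)
    keep = np.hypot(seg[:, 0], seg[:, 1]) > 0
    seg = seg[keep]
    extent = np.ptp(path, axis=0)
    diag = float(np.hypot(*extent))
    if len(seg) < 2:
        return CurveFeatures(0, True, float(extent[0]), float(extent[1]))
    cross = seg[:-1, 0] * seg[1:, 1] - seg[:-1, 1] * seg[1:, 0]
    signs = np.sign(cross[np.abs(cross) > 1e-15 * max(diag, 1.0) ** 2])
    turning = int(np.count_nonzero(np.diff(signs) != 0))
    closed = bool(np.hypot(*(path[0] - path[-1])) <= closure_tol * max(diag, 1e-300))
    return CurveFeatures(turning, closed, float(extent[0]), float(extent[1]))


def plateau_value(curve: CharacteristicCurve) -> float:
    """Structural-entropy plateau of a reference curve.

    The plateau is read at the flattest point of ``Sstr`` versus
    ``ln(scale)``: the index minimizing the absolute central-difference
    slope.  This is robust to the drift that grid truncation induces at
    one end of the scale band for heavy-tailed families.
    """
    s = curve.s_str
    if len(s) < 3:
        return float(np.median(s))
    t = np.log(np.asarray(curve.param_values, dtype=float))
    slope = np.gradient(s, t)
    return float(s[int(np.argmin(np.abs(slope)))])


def oscillation_amplitude(values) -> float:
    """Peak-to-peak amplitude of a 1-D profile (e.g. Sstr vs position)."""
    return float(np.ptp(np.asarray(values, dtype=float)))


def peak_prominences(values, min_prominence: float = 1e-5):
    """Local maxima of a 1-D profile and their prominences.

    Thin wrapper over :func:`scipy.signal.find_peaks` used to count the
    hooks of a scan profile (e.g. the two side maxima — the "M shape" —
    of a scan across a polyp with shadow) and to measure their
    magnitude.

    Returns
    -------
    (numpy.ndarray, numpy.ndarray)
        Peak indices and the corresponding prominences.
    """
    values = np.asarray(values, dtype=float)
    peaks, props = find_peaks(values, prominence=min_prominence)
    return peaks, props["prominences"]
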