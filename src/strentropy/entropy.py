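"""Renyi-entropy quantities of 2-D pixel-intensity distributions.

An image tile is treated as its native probability distribution: the
non-negative pixel intensities ``I_i`` divided by their sum, ``p_i =
I_i / sum(I)``.  From that distribution four numbers summarise shape and
extension:

* the Shannon entropy ``S1 = -sum p_i ln p_i`` (nats),
* the collision (second Renyi) entropy ``S2 = -ln sum p_i**2``,
* the participation ratio ``D = exp(S2) = 1 / sum p_i**2``, the
  effective number of "light" pixels,
* the spatial filling factor ``q = D / N`` with ``N`` the total pixel
  count of the tile.

The structural entropy ``Sstr = S1 - S2`` is the shape information left
after removing the extension information ``ln D``; it satisfies
``0 <= Sstr <= -ln q``, so every distribution maps to a point on or
below the limit line of the ``Sstr(ln q)`` plane.  Distributions of one
shape family (Gaussian, exponential, wave, hemisphere, ...) trace a
characteristic curve on that plane as their scale parameter varies.

All logarithms are natural; every entropy is reported in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntropyPoint",
    "normalize_intensities",
    "shannon_entropy",
    "renyi_entropy",
    "hartley_entropy",
    "participation_ratio",
    "filling_factor",
    "structural_entropy",
    "entropy_point",
]


@dataclass(frozen=True)
class EntropyPoint:
    """Entropy summary of one intensity distribution.

    One ``EntropyPoint`` is one dot on the structural-entropy versus
    log-filling-factor map.

    Attributes
    ----------
    s1 : float
        Shannon entropy in nats.
    s2 : float
        Second Renyi (collision/extension) entropy in nats.
    s0 : float
        Hartley entropy, ``ln`` of the number of strictly positive
        probabilities, in nats.
    d : float
        Participation ratio, the effective pixel count (``1 <= d <= n_total``).
    q : float
        Spatial filling factor ``d / n_total``, in ``(0, 1]``.
    ln_q : float
        ``ln q`` (``<= 0``); for full-support distributions equals ``s2 - s0``.
    s_str : float
        Structural entropy ``s1 - s2`` (``>= 0``), in nats.
    n_total : int
        Total pixel count of the source grid.
    """

    s1: float
    s2: float
    s0: float
    d: float
    q: float
    ln_q: float
    s_str: float
    n_total: int

    def as_dict(self) -> dict:
        return {
            "S1": self.s1,
            "S2": self.s2,
            "S0": self.s0,
            "D": self.d,
            "q": self.q,
            "ln_q": self.ln_q,
            "Sstr": self.s_str,
            "N": self.n_total,
        }


def normalize_intensities(grid, floor_offset: float = 0.0) -> np.ndarray:
    """Normalize a non-negative intensity grid to a probability vector.

    Parameters
    ----------
    grid : array-like
        2-D (or already flat) non-negative intensities.
    floor_offset : float, optional
        Constant added to every intensity before normalization.  A tiny
        positive floor (e.g. ``1e-10``) reproduces the convention of
        avoiding exactly-zero probabilities; the default ``0.0`` relies
        on the ``0 ln 0 = 0`` limit instead.

    Returns
    -------
    numpy.ndarray
        Flat (row-major) probability vector summing to 1.

    Raises
    ------
    ValueError
        If any intensity is negative ("negative intensity") or the grid
        sums to zero ("degenerate distribution").
    """
    values = np.asarray(grid, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("degenerate distribution: empty grid")
    if np.any(values < 0):
        raise ValueError("negative intensity")
    if floor_offset < 0:
        raise ValueError("floor_offset must be non-negative")
    if floor_offset:
        values = values + floor_offset
    total = values.sum()
    if total <= 0:
        raise ValueError("degenerate distribution: all intensities are zero")
    return values / total


def shannon_entropy(p) -> float:
    """Shannon entropy ``-sum p_i ln p_i`` in nats, with ``0 ln 0 := 0``."""
    p = np.asarray(p, dtype=float).ravel()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def renyi_entropy(p, order: float) -> float:
    """Renyi entropy of the given non-negative order, in nats.

    Order 0 is the Hartley entropy ``ln(#{p_i > 0})``, order 1 the
    Shannon entropy (continuity limit), and otherwise
    ``ln(sum p_i**order) / (1 - order)``.  The series is non-increasing
    in the order.
    """
    if order < 0:
        raise ValueError("Renyi order must be non-negative")
    p = np.asarray(p, dtype=float).ravel()
    if order == 0:
        return float(np.log(np.count_nonzero(p > 0)))
    if order == 1:
        return shannon_entropy(p)
    nz = p[p > 0]
    return float(np.log((nz**order).sum()) / (1.0 - order))


def hartley_entropy(p) -> float:
    """Hartley (order-0 Renyi) entropy: ``ln`` of the support size."""
    return renyi_entropy(p, 0)


def participation_ratio(p) -> float:
    """Participation ratio ``D = 1 / sum p_i**2``, the effective pixel count.

    ``D`` ranges from 1 (a single light pixel) to ``N`` (uniform) and
    equals ``exp(S2)``.
    """
    p = np.asarray(p, dtype=float).ravel()
    return float(1.0 / (p**2).sum())


def filling_factor(p, n_total: int | None = None) -> float:
    """Spatial filling factor ``q = D / N`` in ``(0, 1]``.

    ``N`` is the total pixel count of the source grid (the length of the
    probability vector), not the support size.
    """
    p = np.asarray(p, dtype=float).ravel()
    n = p.size if n_total is None else int(n_total)
    return participation_ratio(p) / n


def structural_entropy(p) -> float:
    """Structural entropy ``Sstr = S1 - ln D >= 0`` in nats.

    Zero for any uniform (or single-pixel) distribution: a flat patch
    carries extension information only, no shape information.
    """
    s = shannon_entropy(p) - renyi_entropy(p, 2)
    # exact identities can land an ulp below zero for flat distributions
    return max(s, 0.0)


def entropy_point(grid, floor_offset: float = 0.0) -> EntropyPoint:
    """Compute the full entropy summary of one intensity grid.

    Bundles normalization and all entropy/localization quantities for a
    single tile; deterministic for a fixed grid.
    """
    p = normalize_intensities(grid, floor_offset=floor_offset)
    n_total = p.size
    s1 = shannon_entropy(p)
    sum_sq = float((p**2).sum())
    s2 = -float(np.log(sum_sq))
    s0 = float(np.log(np.count_nonzero(p > 0)))
    d = 1.0 / sum_sq
    q = d / n_total
    return EntropyPoint(
        s1=s1,
        s2=s2,
        s0=s0,
        d=d,
        q=q,
        ln_q=float(np.log(q)),
        s_str=max(s1 - s2, 0.0),
        n_total=n_total,
    )


def ensemble_statistics(intensities: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised entropy summary of a stack of intensity grids.

    Parameters
    ----------
    intensities : numpy.ndarray
        Array of shape ``(n_samples, ...)``; each sample is flattened
        and normalized independently.  All values must be non-negative
        and each sample must have positive sum.

    Returns
    -------
    dict of numpy.ndarray
        Keys ``"S1"``, ``"S2"``, ``"S0"``, ``"D"``, ``"q"``, ``"ln_q"``,
        ``"Sstr"``, each of length ``n_samples``.
    """
    flat = np.asarray(intensities, dtype=float).reshape(len(intensities), -1)
    if np.any(flat < 0):
        raise ValueError("negative intensity")
    totals = flat.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("degenerate distribution in ensemble")
    p = flat / totals
    n = p.shape[1]
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    s1 = -plogp.sum(axis=1)
    sum_sq = (p**2).sum(axis=1)
    s2 = -np.log(sum_sq)
    s0 = np.log(np.count_nonzero(p > 0, axis=1))
    d = 1.0 / sum_sq
    q = d / n
    return {
        "S1": s1,
        "S2": s2,
        "S0": s0,
        "D": d,
        "q": q,
        "ln_q": np.log(q),
        "Sstr": s1 - s2,
    }
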