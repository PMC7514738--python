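"""Randomized distribution ensembles for identity and bound checks.

The entropy identities (``exp(S2) = D``, ``ln q = S2 - S0`` for full
support, ``Sstr = S1 - ln D``) and the printed bounds (``Sstr >= 0``,
``Sstr <= -ln q``, ``0 < q <= 1``) hold for *every* distribution, so
they are exercised on large ensembles of unstructured random grids:
uniform-random non-negative intensities, normalized per grid.
"""

from __future__ import annotations

import numpy as np

from .entropy import ensemble_statistics

__all__ = ["uniform_intensity_ensemble", "ensemble_statistics"]


def uniform_intensity_ensemble(
    n_samples: int, shape=(32, 32), rng=None
) -> np.ndarray:
    """Stack of grids with i.i.d. uniform(0, 1) intensities.

    Parameters
    ----------
    n_samples : int
        Number of grids.
    shape : tuple, optional
        Grid shape, default 32 x 32.
    rng : numpy.random.Generator or int, optional
        Generator or seed; a fixed seed makes the ensemble reproducible.

    Returns
    -------
    numpy.ndarray
        Array of shape ``(n_samples, *shape)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.random((int(n_samples),) + tuple(np.atleast_1d(shape).astype(int)))
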