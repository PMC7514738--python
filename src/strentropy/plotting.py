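"""Optional plotting of the structural-entropy / filling-factor map.

Headless-safe (Agg backend is forced when no display is available);
never required by the computational API or the tests.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .curves import limit_line

__all__ = ["plot_entropy_map"]


def plot_entropy_map(curves, ax=None, show_limit=True, show_references=False):
    """Plot curves on the ``Sstr(ln q)`` plane with the limit line.

    ``curves`` is an iterable of objects exposing ``path()`` (both
    characteristic curves and scan curves do) or plain ``(n, 2)``
    arrays of ``(ln q, Sstr)`` pairs.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    paths = []
    for curve in curves:
        path = curve.path() if hasattr(curve, "path") else np.asarray(curve)
        label = getattr(curve, "family", None) or getattr(curve, "channel", None)
        ax.plot(path[:, 0], path[:, 1], marker=".", ms=3, lw=1, label=label)
        paths.append(path)
    if show_limit and paths:
        lo = min(p[:, 0].min() for p in paths)
        line = limit_line(np.linspace(min(lo, -0.1), 0.0, 50))
        ax.plot(line[:, 0], line[:, 1], "k-", lw=2, label=r"$S_{str}=-\ln q$")
    if show_references:
        from .curves import REFERENCE_CONSTANTS, reference_curve

        for name in REFERENCE_CONSTANTS:
            ref = reference_curve(name, np.geomspace(3, 25, 12), grid_size=256)
            path = ref.path()
            ax.plot(path[:, 0], path[:, 1], "--", lw=1, label=name)
    ax.set_xlabel(r"$\ln q$")
    ax.set_ylabel(r"$S_{str}$ [nats]")
    if any(line.get_label() and not line.get_label().startswith("_")
           for line in ax.lines):
        ax.legend(fontsize=8)
    return ax
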