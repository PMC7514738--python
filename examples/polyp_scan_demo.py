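"""Sliding-tile scan across a synthetic polyp.

Builds a 160x400 scene with a polyp of diameter 120 px (hemisphere
height 120, Gaussian shadow depth 60, flat offset 80 — a realistic
green-channel configuration), scans the center row with a 50x50 tile,
and summarises the scan: the Sstr(position) profile forms an "M" with
two hooks where the tile straddles the shadow ring, and the
(ln q, Sstr) path closes into a loop around the polyp.
"""

import numpy as np

from strentropy import TileSpec, curve_features, polyp_model, slide_scan
from strentropy.curves import peak_prominences

scene = polyp_model((160, 400), radius=60, height=120, depth=60, offset=80)
curve = slide_scan(scene, TileSpec(tile_size=50))

peaks, proms = peak_prominences(curve.s_str, min_prominence=1e-4)
feats = curve_features(curve, closure_tol=0.05)

print(f"scan positions: {len(curve)} (tile 50, stride 1, row scan)")
print(f"Sstr range: {curve.s_str.min():.4f} .. {curve.s_str.max():.4f}")
print(f"local maxima of Sstr(position): {len(peaks)} "
      f"at tile centers {np.round(curve.positions[peaks], 1).tolist()}")
print(f"hook prominences: {np.round(proms, 4).tolist()}")
print(f"(ln q, Sstr) path closes into a loop: {feats.loop_closed}")
print()
print("The two dominant maxima flank the polyp center (position ~200):")
print("each marks the tile positions where the shadow ring dominates")
print("the tile — the 'M shape' signature of a polyp with shadow.")
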