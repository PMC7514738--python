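"""Entropy point of small intensity grids.

Builds three tiny distributions and prints their Shannon entropy S1,
collision entropy S2, participation ratio D, filling factor q and
structural entropy Sstr.  A flat patch sits at the origin of the
Sstr(ln q) map (no shape information, full extension); concentrating
the light on fewer pixels lowers q; unequal but spread-out intensities
raise Sstr.
"""

import numpy as np

from strentropy import entropy_point

grids = {
    "uniform 4x4": np.ones((4, 4)),
    "two pixels 3:1": np.array([[3.0, 1.0]]),
    "single light pixel (10x10)": np.pad(np.ones((1, 1)), ((0, 9), (0, 9))),
}

print(f"{'grid':<28} {'S1':>8} {'S2':>8} {'D':>7} {'q':>6} {'ln q':>8} {'Sstr':>8}")
for name, grid in grids.items():
    pt = entropy_point(grid)
    print(
        f"{name:<28} {pt.s1:8.4f} {pt.s2:8.4f} {pt.d:7.2f} "
        f"{pt.q:6.3f} {pt.ln_q:8.4f} {pt.s_str:8.4f}"
    )

print()
print("The uniform grid has Sstr = 0 and q = 1 (origin of the map);")
print("the 3:1 pair keeps full support but gains shape info (Sstr ~ 0.0923);")
print("the single light pixel has q = 1/100 and again Sstr = 0.")
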