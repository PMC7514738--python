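"""Preprocessing chain on a tilted, glared synthetic scene.

Builds a wave scene with an intensity ramp (tilt, imitating the
darkening toward distant bowel regions) and a saturated glare disc,
then runs reflection removal -> histogram stretching -> box-mean
background subtraction.  The effect is judged on the sliding-tile
Sstr(position) profile: before preprocessing the tilt and glare
distort it away from the clean wave's profile; after preprocessing the
wave signature is largely recovered.
"""

import numpy as np

from strentropy import TileSpec, apply_tilt, slide_scan, straight_wave
from strentropy.scan import preprocess, stretch_histogram

wave = 200 * straight_wave((200, 400), wavelength_x=100)
scene = apply_tilt(wave, slope=0.5)  # darkening toward one side
glare = scene.copy()
x, y = np.meshgrid(np.arange(400) - 320, np.arange(200) - 60)
glare[x**2 + y**2 < 10**2] = glare.max() * 1.2  # specular highlight

clean, meta = preprocess(glare, background_size=150, saturation_fraction=0.9)

spec = TileSpec(tile_size=50)
pure = slide_scan(stretch_histogram(wave) + 1e-9, spec).s_str  # reference
before = slide_scan(glare, spec).s_str
after = slide_scan(clean + 1e-9, spec).s_str


def rms(a, b):
    return float(np.sqrt(np.mean((a - b) ** 2)))


print("steps:", " -> ".join(meta["steps"]))
print(f"saturated pixels replaced: {meta['saturated_pixels']}")
print(f"rms deviation of Sstr(position) from the clean wave scan:")
print(f"  before preprocessing: {rms(before, pure):.4f}")
print(f"  after preprocessing:  {rms(after, pure):.4f}")
print()
print("Reflection removal and background subtraction strip the glare")
print("and the tilt, so the processed scan tracks the wave's own")
print("profile — the state the characteristic-curve references assume.")
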