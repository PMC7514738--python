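# strentropy

Structural entropy and spatial filling factor analysis of 2-D
intensity distributions, aimed at texture characterization of
colonoscopy-style images: bowel-wall waves, roundish polyps and the
shadow valleys around them.

## The quantities

An image tile is its own probability distribution: non-negative pixel
intensities normalized by their sum, `p_i = I_i / Σ I_i`. From the
Rényi entropy series `S_n = ln(Σ p_i^n) / (1 − n)` (natural logarithm,
nats) the package computes

- `S1` — Shannon entropy (the `n → 1` limit),
- `S2 = ln D` — collision/extension entropy, with
  `D = 1 / Σ p_i²` the participation ratio (effective number of light
  pixels),
- `q = D / N` — the spatial filling factor, the fraction of the
  `N`-pixel tile the distribution effectively occupies,
- `S_str = S1 − S2` — the structural entropy: the shape information
  remaining after the extension information `ln D` is removed.

Both quantities are scale- and resolution-independent, and every
distribution satisfies `0 ≤ S_str ≤ −ln q`. Distributions of one shape
family trace a characteristic curve on the `S_str(ln q)` plane as
their scale parameter varies — the radially symmetric 2-D Gaussian,
exponential and second-order power-law densities plateau at the
closed-form constants `1 − ln 2`, `2 − ln 4` and `2 − ln 3` — so the
position of measured points relative to those curves identifies the
underlying structure.

The package provides the entropy core, deterministic generators for
the model surfaces (straight/circular waves, tilts, half-ellipsoids,
generalized-Gaussian shadows, the polyp model, additive and
multiplicative superpositions), a characteristic-curve sweep engine,
sliding-tile image scanning, and an endoscopy-style preprocessing
chain (specular-reflection removal, histogram stretching, box-mean
background subtraction).

## Worked example

Scanning a synthetic polyp scene (hemisphere of diameter 120 px,
height 120, Gaussian shadow of depth 60, flat offset 80) with a 50×50
sliding tile:

```python
from strentropy import TileSpec, curve_features, polyp_model, slide_scan
from strentropy.curves import peak_prominences

scene = polyp_model((160, 400), radius=60, height=120, depth=60, offset=80)
curve = slide_scan(scene, TileSpec(tile_size=50))
peaks, proms = peak_prominences(curve.s_str, min_prominence=1e-4)
print(len(curve), len(peaks), curve.positions[peaks])
print(curve_features(curve, closure_tol=0.05).loop_closed)
```

prints (see `examples/polyp_scan_demo.py` for the narrated version):

```
scan positions: 351 (tile 50, stride 1, row scan)
Sstr range: 0.0000 .. 0.0436
local maxima of Sstr(position): 2 at tile centers [142.5, 256.5]
hook prominences: [0.0436, 0.0436]
(ln q, Sstr) path closes into a loop: True
```

The two structural-entropy maxima flank the polyp center at
position ≈ 200: they mark the tile positions where the shadow ring
dominates the tile. This two-hook "M shape", together with the closed
loop the scan traces on the `S_str(ln q)` plane, is the polyp
signature that distinguishes it from the periodic loops of bowel-wall
waves.

The other scripts in `examples/` each demonstrate one capability:
entropy basics, model surfaces, reference-curve plateaus, wave sweeps
and the preprocessing chain. A thin CLI wraps the same functions:

```sh
strentropy entropy image.png
strentropy scan image.png --tile-size 50 -o scan.csv
strentropy reference --family gaussian -o ref.csv
```

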