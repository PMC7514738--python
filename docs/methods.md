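# Methods

## Model

A grayscale tile of `N` pixels is identified with the probability
distribution obtained by dividing its non-negative intensities by
their sum. All entropies use the natural logarithm (unit: nats) with
the prefactor fixed to one. The summary of one tile is the tuple
(`S1`, `S2`, `S0`, `D`, `q`, `ln q`, `S_str`):

- `S1 = −Σ p_i ln p_i`, with the `0 ln 0 := 0` limit taken exactly;
- `S_n = ln(Σ p_i^n)/(1 − n)` for general Rényi order `n ≥ 0`, with
  `S0 = ln(support size)` and `S1` as the continuity limit;
- `D = 1/Σ p_i²  = exp(S2)`, the participation ratio — an effective
  count of the "light" pixels, between 1 (single pixel) and `N`
  (uniform);
- `q = D/N ∈ (0, 1]`, the spatial filling factor; for full-support
  distributions `ln q = S2 − S0` exactly;
- `S_str = S1 − S2 ≥ 0`, the structural entropy, bounded by
  `S_str ≤ −ln q`.

These identities are dimensionless, invariant under intensity
rescaling and under any permutation of pixels: the quantities see the
intensity histogram only, not the spatial arrangement. Spatial
structure enters through the *tile*: sliding a window across an image
and plotting the per-tile points traces a curve on the
`S_str(ln q)` plane whose geometry (hooks, loops, periodicity) does
reflect arrangement.

### Zero probabilities

Zero intensities are handled by the exact limit rather than by a
numerical floor. A `floor_offset` option on `normalize_intensities` /
`entropy_point` adds a constant (typically `1e-10`) before
normalization for workflows that prefer strictly positive
probabilities; with a floor that small the two conventions agree far
below every tolerance used here. Sums are accumulated in double
precision; against naive-loop summation the library agrees to 1e-12
on small grids and no compensated summation is needed at the grid
sizes used (≤ 10⁶ pixels).

## Model surfaces

Generators produce deterministic non-negative fields on centered
pixel grids (`x = col − (n_cols−1)/2`, `y = row − (n_rows−1)/2`;
phases in degrees):

- **Straight wave** `A sin(2πx/Tx + 2πy/Ty + φ) + 0.5 + B` and
  **circular wave** `A sin(√[(2π(x−x0)/Tx)² + (2π(y−y0)/Ty)²] + φ) +
  0.5 + B`. The amplitude defaults to `A = 0.5`, making the range
  `[B, 1+B]`; amplitudes above `0.5 + B` are rejected as they would
  violate non-negativity. A wave whose center is a few tile sizes away
  is locally indistinguishable from a straight front — the realistic
  case for bowel folds seen in perspective.
- **Tilt**: a plane ramp (straight fronts, direction perpendicular to
  the wavefront by default) or a cone with apex at the wave center
  (circular fronts), shifted so the added ramp is everywhere ≥ 0. In
  the sweep families the slope is parameterized as
  wavelength/`tilt_ratio` per pixel. The literature phrasing of this
  ratio is ambiguous; the convention here is recorded as such and
  nothing quantitative depends on it.
- **Half ellipsoid** `max(√(R² − ((x−rx)/Rx)² − ((y−ry)/Ry)²), B)`:
  peak `R`, elliptical footprint with semi-axes `R·Rx`, `R·Ry`, flat
  background `B` outside.
- **Generalized-Gaussian shadow** `exp(−ρ^(α/2))` with
  `ρ = (x−rx)²/σx² + (y−ry)²/σy²`; `α = 2` is exactly Gaussian,
  larger `α` is flatter-centered with a faster falloff. At `ρ = 1` the
  value is `e⁻¹` for every `α`.
- **Polyp model** `offset + height·(hemisphere/R) − depth·shadow`,
  shadow centered on the bump with `σ = R` by default, clamped below
  at a floor (default 0). Its center cut is a bump flanked by two
  minima below the offset level — the ditch/shadow profile of real
  polyps. A configuration whose unclamped minimum dips below
  `−offset` clamps a large area and logs a warning; the realistic
  channel configurations (offsets ≥ shadow depth, e.g. offset 80,
  height 120, depth 60 for a 120-px polyp) never clamp.
- **Superpositions**: weighted sums and elementwise products. For
  outer-product (separable) fields the 2-D `S_str` and `ln q` are
  exactly the sums of the 1-D profile values; for generic fields this
  additivity fails, and for additive superpositions the components
  are only visible when one dominates.

## Characteristic curves

`parameter_sweep` evaluates a surface family over an ordered primary
parameter (optionally crossed with a secondary parameter, one curve
per secondary value) and returns ordered entropy points. Default
sweep densities in the examples are 25 points per primary parameter.
Sweeps are deterministic and bit-reproducible.

`reference_curve` evaluates the radially symmetric densities

| family | density | continuum `S_str` |
|---|---|---|
| gaussian | `exp(−r²/s²)` | `1 − ln 2 ≈ 0.306853` |
| exponential | `exp(−r/s)` | `2 − ln 4 ≈ 0.613706` |
| power_law_2 | `(1 + r²/s²)⁻²` | `2 − ln 3 ≈ 0.901388` |

on an `N×N` grid. The constants follow from the closed-form integrals
of `p ln p` and `p²` and were re-derived analytically and numerically
before being frozen into tests. Scales outside `[3, N/10]` are
flagged: below 3 px discretization bites, above `N/10` truncation
does. Within the band the Gaussian is exact to machine precision and
the exponential to ~0.3%. The power law is special: its `r⁻⁴` tail
holds ~1% of the mass beyond the grid edge already at `s ≈ 25` on a
512 grid, which depresses `S_str` by several percent at the
large-scale end. The plateau of a reference curve is therefore read
at its flattest point (`plateau_value`: minimal |dS_str/d ln s|),
which for the power law sits at the small-scale end (within 0.5% of
`2 − ln 3`) and for the other families anywhere in the band. This
estimator is applied uniformly to all families.

`curve_features` summarises a path on the `S_str(ln q)` plane:
turning points are sign changes of the discrete curvature after a
3-point moving average, loop closure means first and last points
within 1% (configurable) of the path diagonal. For scan profiles,
hook magnitudes are measured as peak prominences of
`S_str(position)` (scipy `find_peaks`). Loop *area* is deliberately
not used as a magnitude: for mirror-symmetric scenes (straight waves,
centered polyps) the path exactly retraces itself and encloses zero
area regardless of how pronounced the hooks are.

## Scanning and preprocessing

`slide_scan` moves a square tile (default 50×50, stride 1) along a
row or column; only positions where the full tile fits are used
(`⌊(L − tile)/stride⌋ + 1` positions), each tile is normalized
independently, and positions are reported as tile centers. All-zero
tiles are flagged, logged and excluded. `fixed_tiling` covers the
image with non-overlapping tiles from the top-left, dropping partial
edge tiles. Color channels are scanned independently; there is no
luminance conversion, since the channels emphasise different anatomy.

The preprocessing chain runs in the order reflection removal →
histogram stretching → background subtraction, recorded in the
returned metadata:

- **Reflection removal**: pixels at or above a saturation fraction
  (default 0.95) of the dynamic-range maximum are replaced by the
  mean of non-saturated pixels in a growing neighborhood (≥ 8 valid
  pixels); frames more than half saturated are rejected. This
  threshold-and-local-mean fill is a minimal, explicit choice — the
  procedure is not standardized in the source literature.
- **Histogram stretching**: linear map of `[min, max]` onto
  `[0, out_max]`. Affine, not linear — it changes entropy points
  whenever the minimum is positive, which is intended (it removes the
  constant offset).
- **Background subtraction**: subtract a `k×k` box mean (reflect
  padding; defaults 100 and 200 px, matching image sizes around
  1000 px) and shift to ≥ 0. A filter size near the polyp diameter
  suppresses the polyp itself; about twice the diameter preserves it
  while still removing tilt.

## Offset behavior (a non-obvious point)

`S_str` of a wave is **not** monotone in the offset `B`: from a
negligible floor it first *rises* (by a few percent up to `B` of a
few hundredths) before the flattening of the distribution drives it
to zero for large `B`. Verified by independent naive-loop summation.
Consequently the qualitative "offset increases wave scan magnitudes"
behavior holds in the small-offset regime (floor → percent level),
and the tests assert it there ({1e-10, 1e-3, 1e-2}), while the
strict decrease is asserted in the flattening regime (`B ≥ 0.1`).
For the polyp scene the offset dilutes contrast monotonically (hook
prominences fall as the flat offset rises), asserted on the
unclamped configuration with offsets {50, 80, 150}.

## What the synthetic scenes do and do not show

The generators reproduce the coarse geometry of bowel-wall frames —
periodic folds, roundish bumps, shadow rings, tilts, specular
glare — with exact, noise-free fields. They do not emulate fine-scale
pit-pattern texture, sensor noise, compression artifacts, color
cross-talk or lens distortion. Passing tests therefore demonstrate
that the estimator and the scanning machinery behave as the theory
predicts on the modeled structures, not that any fixed threshold
separates polyps from background on real frames; on real images the
curves are additionally distorted by the neglected fine structure.

## Problem sizes

Default test and script sizes: 10⁴ random 32×32 grids for the
identity/bound ensembles; 512×512 grids for reference plateaus;
scenes up to 200×400 with 50×50 tiles for scans; wave sweeps up to
800×800 for the tile-size stability family. These sizes put every
quantitative check well inside its asymptotic regime while keeping
the full suite fast on a single CPU.

## Known limitations

- The power-law reference curve is trustworthy only where truncation
  is small (scale ≲ N/50 on an `N×N` grid); the plateau estimator
  handles this but per-point comparisons at large scales will be
  biased low.
- `remove_reflections` loops over saturated pixels in Python; it is
  meant for the sparse glare of endoscopy frames, not for images that
  are largely saturated.
- The tilt-ratio convention is a recorded choice, not a established
  standard; compare tilted sweeps only within this package.
- Entropy quantities see only the histogram of each tile; two tiles
  with identical histograms but different spatial arrangements are
  indistinguishable at the single-tile level.
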