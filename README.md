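# printbench

Quantitative print-quality benchmarking for extrusion bioprinting.

Extrusion-printed hydrogel scaffolds are routinely judged by eye, even
though the geometry that matters for cell viability — open pores, square
corners, strands that match the nozzle — is measurable.  `printbench`
implements the standard benchmark suite as a reusable, tested pipeline:

* **benchmark toolpaths** — a chirped square-wave serpentine for the
  filament-fusion test, square lattice grids, collapse-test lines over a
  pillar fixture, and straight lines, serialized as volumetrically
  calibrated G-code (the "diameter trick": a declared filament diameter of
  2/√π = 1.12838 mm makes 1 mm of commanded E exactly 1 mm³, and a pump
  rotation distance of 10 mm³/rev maps a 10 mm E command to one motor turn);
* **a synthetic deposition renderer** — seeded top-view and side-view
  images of deposited filaments with multiplicative spreading (die swell),
  band-limited boundary roughness, corner rounding and strand fusion,
  parabolic sag, illumination gradient and sensor noise, standing in for
  camera photographs so the analysis chain can be tested against known
  ground truth;
* **a Fiji-style segmentation workflow** — 8-bit grayscale, global/Otsu
  thresholding with pores-bright polarity, connected-component particle
  analysis with sub-pixel perimeters, size/circularity/border filtering,
  and porosity over a stated field of view;
* **the metric set** — with `w_ext` the printed width, `d_nozzle` the bore,
  `p_ext`/`p_th` the measured and smooth perimeters, and `L`, `A` a pore's
  perimeter and area:

  | metric | definition | ideal |
  |---|---|---|
  | Spreading ratio | SR = w_ext / d_nozzle | 1.0 |
  | Uniformity ratio | UF = p_ext / p_th | 1.0 |
  | Printability index | Pr = L² / (16 A) | 1.0 (square pore) |
  | Collapse angle | θ at the supports of a suspended filament | 0° |
  | Collapse rate | Cf = 100 (A_ct − A_ca) / A_ct | 0 % |
  | Apparent yield stress | σ₀ = ρ g L / sin θ (L = half gap) | — |
  | Fusion spacing | l_min = smallest open gap; l_t = strand width | nozzle-limited |
  | Pore size | hydraulic radius A / P; porosity % | design values |

  The σ₀ inversion comes from the filament-collapse force balance
  θ = sin⁻¹(ρgL/σ₀); it is *apparent* because the model ignores the
  deposited volume.

A benchmark run compares a pneumatic system preset against a screw-driven
(positive-displacement) extruder swept over volumetric extrusion factors
from 50% to 100%, reproducing the logic of under-extruding to compensate
viscoelastic die swell.

## Worked example

```python
import numpy as np
from printbench import (GridParams, grid_toolpath, DepositionModel, render_topview,
                        binarize, label_particles, filter_particles, porosity,
                        DEFAULT_PORE_FILTER, printability_index, SagModel,
                        render_sideview, collapse_angle, apparent_yield_stress,
                        MaterialParams)

# a 30 x 30 mm, 5 mm pitch grid printed with strong die swell (SR 1.85)
toolpath = grid_toolpath(GridParams(outer_size=30, pore_pitch=5, n_layers=2))
image = render_topview(toolpath, DepositionModel(spread_ratio=1.85, seed=0), scale=20)
mask = binarize(image, "otsu", polarity="bright")
pores = filter_particles(label_particles(mask), DEFAULT_PORE_FILTER)
print(f"pores: {len(pores)}")
print(f"porosity: {porosity(mask, roi=(0, 0, 30, 30)):.2f} %")
print(f"mean Pr: {np.mean([printability_index(p) for p in pores]):.3f}")

# a filament sagging 3.151 mm over a 32 mm collapse-test span
side = render_sideview(SagModel(span=32, max_sag=3.151, filament_thickness=0.8), scale=20)
theta = collapse_angle(side).theta_deg
sigma = apparent_yield_stress(theta, MaterialParams(), half_gap=16)
print(f"deflection angle: {theta:.2f} deg -> apparent yield stress: {sigma:.0f} Pa")
```

prints

```
pores: 36
porosity: 72.25 %
mean Pr: 0.987
deflection angle: 21.37 deg -> apparent yield stress: 431 Pa
```

All 36 pores of the lattice are recovered; the swollen 0.76 mm strands
occlude part of the designed 91.8% open area, leaving 72% porosity; the
pores stay square (Pr ≈ 1); and the 21.4° measured deflection inverts to a
yield stress of ~430 Pa — the gravitational load a 0.016 m half-span
filament of water-dense ink must resist at that angle.

## Command line

```sh
printbench run --seed 1 --out runs/demo          # full default benchmark
printbench generate --out toolpaths/              # G-code + vertex tables
printbench analyze photo.png --scale 12.5 --kind grid --roi 0 0 30 30
printbench report runs/demo --metric porosity_pct --baseline GridP
```

`analyze` accepts your own photographs given a pixels-per-mm scale;
`run` writes per-sample G-code, images, masks, particle tables and a
CSV/JSON report with config-hash provenance.

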