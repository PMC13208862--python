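# Methods

## Pipeline overview

`printbench` treats printability assessment as a measurement chain:
commanded geometry (toolpath) → deposited material (deposition model) →
observation (rendered raster image) → segmentation (binary mask, particles)
→ metrics.  Every stage is deterministic given a seed, so the analysis
operators can be validated against the ground truth the earlier stages
carry along in metadata.

## Benchmark geometry

**Chirped serpentine.**  The fusion-test trajectory follows
f(x) = A·sgn(sin(F·|x|ⁿ)) with defaults A = 10 mm, F = 0.05, n = 2.1 over
x ∈ [0, 50] mm: horizontal rails at ±A joined by vertical legs at each
sign change of the inner sinusoid.  (A factor of 10 inside the sgn is
sometimes written in this form; it is mathematically inert —
sgn(10u) = sgn(u) — and is treated as such.)  Because F·xⁿ is strictly
increasing, the leg positions are the closed-form roots x_k = (kπ/F)^(1/n);
with n > 1 the leg spacing decreases monotonically with x (from 2.81 mm
down to 0.41 mm at the defaults), sweeping a whole range of commanded line
spacings l_s in one continuous print.  The convention sgn(0) := +1 starts
the pattern on the +A rail.  A `sample_step` parameter guards against
configurations whose spacing would fall below the stated sampling
resolution.

**Grid.**  n = outer/pitch + 1 lines per direction per layer, boundary
lines included (30 mm / 5 mm pitch → 7 + 7 lines enclosing 36 pores of
nominally 5 mm pitch), drawn boustrophedon with travel hops, two layers at
0.51 mm layer height by default.

**Collapse fixture.**  A single straight line over pillars (default
2 mm wide, 10 mm tall — values needed for rendering; only the gaps matter
to the metric) separated by strictly increasing gaps, default
1–16 mm doubling.  A zero gap is accepted but flagged degenerate (a fully
supported line).

**Volumetric G-code.**  With the theoretical filament diameter set to
2/√π = 1.12838 mm the implied cross-section is exactly 1 mm², so the
E axis counts mm³ directly; a rotation distance of 10 mm³/rev maps E = 10
to one pump revolution.  Each extrude segment increments E by
length × width × layer height × extrusion factor.  Dialect: G21, G90,
absolute E (M82), feedrate in mm/min, 4-decimal formatting — fixed so
round-trip tests are exact to formatting precision.

## Deposition model (what the renderer emulates)

The renderer is a geometric stand-in for camera photographs of deposited
ink, dark on a light background, 8-bit, with an explicit pixels-per-mm
scale recorded in a JSON sidecar (real photographs rarely state their
scale; making it explicit avoids fiducial inference).  It reproduces the
statistical structure the analysis assumes:

* **Spreading**: strands are drawn at commanded width × spread ratio.
  The screw presets interpolate the deposited width linearly from 0.45 mm
  at 50% extrusion factor to 0.76 mm at 100% (SR 1.10–1.85 on a 0.41 mm
  nozzle); the pneumatic preset uses SR 1.82.
* **Boundary roughness**: each side of a strand is displaced along its
  normal by seeded band-limited noise (white noise on control points half
  a wavelength apart, Gaussian-smoothed, spline-interpolated, normalized
  so the RMS displacement equals the stated amplitude).  Zero-mean
  displacement raises UF without changing the mean width, which is what
  lets UF isolate roughness from spreading.  Preset amplitudes (0.08 mm
  pneumatic, 0.055 mm screw, 0.4 mm wavelength) place the presets at
  UF ≈ 1.04 and ≈ 1.02 respectively.
* **Fusion and corner rounding**: a grayscale morphological closing of
  radius max(fusion_gap/2, corner_round_radius) merges strands whose
  edge-to-edge distance is at most the fusion gap and fills concave
  crossing corners.  This is a deliberate topological model — the fusion
  analysis only needs open/closed gap states and widths — not a
  free-surface fluid simulation.
* **Side-view sag**: the filament underside rests on the pillar tops at
  the supports and follows a parabola (uniform-load, small-deflection
  limit) of stated midspan sag s; the support slope is then exactly 4s/L.
* **Acquisition imperfections**: a linear illumination ramp (left edge
  brighter by 1 + gradient) and additive Gaussian intensity noise, both
  seeded.

Rendering is anti-aliased: edge pixels carry fractional ink coverage, so
sub-pixel boundary information survives into the 8-bit image the way
optical blur preserves it in a real photograph.

What the model does **not** emulate: viscoelastic free-surface dynamics,
3-D layer stacking and occlusion, stringing/dragging artifacts, specular
reflections, perspective and lens distortion.  Passing tests therefore
demonstrate that the *measurement chain* is correct and unbiased on
images with known structure; they do not validate rheological predictions
about any particular ink.

## Segmentation conventions

* Grayscale via standard luminance weights; global threshold fixed or
  Otsu (256-bin); polarity `bright` segments pores, `dark` segments ink;
  the applied threshold is recorded in the mask provenance.
* Connectivity: 8-connected foreground with implicit 4-connected
  background (the standard pairing that avoids checkerboard paradoxes).
* Areas are pixel counts / scale²; centroids in mm, top-left origin,
  y down, pixel centers at (index + 0.5)/scale.
* **Perimeter estimator**: polygonal arc length of the marching-squares
  contour at the 0.5 iso-level, with two corrections.  A Gaussian
  smoothing of the binary field (σ adaptive, 0.8–1.6 px with the region's
  minor dimension) suppresses the staircase bias that makes the raw
  contour overestimate a digitized disk by ~6%, and a half-pixel
  Minkowski offset (+π px on the outer contour, −π on holes) maps the
  pixel-center contour onto the pixel-area boundary that smoothing
  corners would otherwise undercut.  Measured bias: ≤ 0.2% on rectangles,
  +1.6% on disks, ≤ 2% on ellipses and rotated squares at ≥ 10 px/mm —
  naive pixel-edge counting is up to ~27% high on oblique boundaries and
  would corrupt Pr, UF and hydraulic radius.
* Circularity 4πA/P² is capped at 1.05 to absorb estimator overshoot on
  tiny specks; hydraulic radius is A/P by construction.
* **Filter presets**: the default pore filter is min 2.5 px² plus border
  exclusion with a fully permissive circularity window.  The classic
  Fiji-style preset (circularity 0.00–0.10) is provided as
  `FIJI_PORE_FILTER`, but note an ideal square pore has circularity
  ≈ 0.785 and would be excluded by that window; whether ragged real pore
  boundaries fall below 0.10 cannot be decided from synthetic data, so
  both presets are exposed and the permissive one is the default.

## Metric conventions

* **Line width** is densitometric: the per-column integral of ink
  fraction, which stays sub-pixel accurate where a binary run-length
  count is quantized to whole pixels (±0.5 px systematic for an
  axis-aligned strand — a 0.03 error in SR at 40 px/mm).  Filaments are
  rotated to horizontal first; 5% end margins and zero-width (broken)
  sections are excluded, the latter counted and reported.
* **UF** uses p_th = 2·length + 2·mean *measured* width, not the nozzle
  diameter — so a smooth but swollen filament scores UF = 1 while SR
  captures the swelling.
* **Collapse angle**: per-column coverage-weighted centerline (ignoring
  sub-threshold coverage so background noise cannot bias it), then a
  parabola fitted over a 2 mm window inward from each support with the
  tangent slope evaluated *at the support*; θ is the mean of the two
  absolute angles.  A straight-line fit over a finite window was
  considered and rejected: it estimates the mean slope over the window,
  which for a parabolic centerline underestimates the support tangent by
  the factor (1 − 3w/4L) — ~6% at w = 2 mm, L = 32 mm, an 0.5° error on a
  9° deflection — while the quadratic fit is exact for the sag model and
  its recovered angles are within 0.15° under rendering noise.
* **Collapse rate**: A_ct = span × reference depth; the enclosed area is
  integrated between the pillar-top chord and the filament's *lower*
  boundary (sub-pixel, from the anti-aliased edge), which rests on the
  pillar tops at the supports — so a parabola of sag s gives
  Cf = 100·(2s)/(3H) exactly and the filament's own thickness does not
  enter.  (Whether the real-image analysis includes the filament
  cross-section in A_ca is ambiguous; this convention is declared
  instead.)
* **Fusion**: a gap is open when a background corridor spans ≥ 90% of the
  leg length between adjacent commanded leg positions (robust to
  single-pixel bridges; threshold configurable); l_min is the smallest
  commanded spacing among open gaps; l_t averages free-standing leg
  widths, excluding rows fused into a neighbour and legs flagged missing
  (> 10% of rows without ink).
* **Yield stress inversion**: σ₀ = ρgL/sin θ with L in metres; defaults
  ρ = 1000 kg/m³ (hydrogel inks are water-dense), g = 9.81 m/s².  With
  the characterized deflections 21.5°/14.2°/9.04° over a 16 mm half-gap
  this yields 428/640/999 Pa.  θ → 0 raises an error (the estimate is
  unbounded: yield stress above the measurable range for that span);
  angles are reported in degrees, stresses in Pa.
* **Grid porosity** is measured over the grid's outer square as ROI.  For
  7 + 7 strips of width w on a 30 mm square the two boundary strips lie
  half inside that ROI, so the closed-form ink area is 2·6·30·w − 36w²
  (the full-strip form 420w − 49w² applies only to an expanded field of
  view); the strand-width estimate inverts this quadratic from the
  measured ink fraction.

## Benchmark orchestration

All randomness flows from one master seed, expanded per sample by hashing
the sample name (so adding or removing samples never perturbs the
others); replicates (default n = 3) increment only the noise seed, since
no other per-replicate variance source is specified for synthetic data.
Reports are written as CSV and JSON with a canonical config hash, the
seed and the package version; per-sample failures are recorded as rows
and do not abort the run.  Two runs with the same config are
byte-identical.

## Problem sizes and numerical choices

Default render scale is 20 px/mm (a 30 mm grid is a ~690 px field);
sub-pixel-sensitive ratios (SR recovery at ±0.02) use 40 px/mm.  Lines
are measured over 30 mm; the parameter-recovery sweep covers
SR ∈ {1.0, 1.2, 1.5, 1.85} × roughness ∈ {0, 0.02, 0.05} mm.  Renders
raise an error below 10 px/mm or when a strand would span < 2 px, and
side views require ≥ 3 px across the filament.  Degenerate inputs
(constant image under Otsu, split filaments in a UF window, empty gap
lists, inverted filter ranges) raise rather than return silent defaults.

## Known limitations

* The deposition model is geometric; absolute porosity/fusion values for
  a real ink depend on rheology the model does not contain, so
  cross-system comparisons on synthetic data validate orderings and
  trends, not absolute agreement with any particular print.
* The perimeter estimator's +1.6% disk bias propagates to ~+3% in Pr for
  strongly rounded pores; square-pore Pr is accurate to < 1.5%.
* The collapse analysis assumes a single unbroken filament per side view
  and a parabolic sag family; rupture is flagged, not measured.
* Multi-layer grids are rendered as a top-view union; layer-height
  effects on strand bonding (discontinuities at low extrusion factors)
  are outside the model.
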