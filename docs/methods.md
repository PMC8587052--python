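# Methods

## Problem and model

A 5×5 array of PCR tubes is imaged by four fixed cameras, each emphasising
one overlapping 3×3 quadrant. Per camera the plate-to-image transform is
modeled as a **pure rigid rotation about the plate center tube** — no lens
distortion, perspective, or scale correction. This is a deliberate modeling
choice: the rig's short, centered optical paths make distortion small, and
everything downstream (uniform-lattice residuals, bilinear center
reconstruction) is built on that assumption. If a real deployment showed
lattice residuals approaching the tube-spacing tolerance (≥1.5 px), a
homography stage would be the first thing to add; it is intentionally out
of scope here.

### Coordinate and angle conventions

Pixels are 0-based, x rightward, y downward; sub-pixel positions are
continuous coordinates at pixel centers, so an H×W image has center
((W−1)/2, (H−1)/2). Angles are degrees, counterclockwise-positive *as
displayed* in this y-down frame. A quadrant's `rotation_angle` is defined
operationally: **the CCW rotation that must be applied to the camera image
to align the tube grid with the plate axes**. The synthetic renderer
therefore draws the grid rotated clockwise-as-displayed by that amount, and
`estimate_rotation(render(θ)) = θ` holds by construction. (The equivalent
statement "the grid appears rotated CW by θ" is the same convention; we
standardize on the correction direction because that is what registration
consumes.)

## Synthetic scenes

The generator emulates, per camera: anti-aliased filled disks (linear
coverage weighting `clip(r + 0.5 − d, 0, 1)` at the boundary, so sub-pixel
centroids are meaningful) added on a uniform background; a radial
multiplicative vignette `1 − v·(ρ/ρ_max)²` about the image center; additive
Gaussian sensor noise; clipping and integer quantization at the configured
bit depth. Defaults and why:

| parameter | default | rationale |
|---|---|---|
| frame | 1440×1120 px | smallest 4:3-ish frame in which the full 25-circle mark sheet fits at any rotation with the paper-scale pitch and aim offsets |
| grid pitch | 161 px | matches the device's per-tube ROI pitch, so registration and quantification run at native scale |
| tube radius | 64 px | comfortably contains the 80 px averaging square's half-diagonal (56.6 px) plus interpolation blur and rounding slack |
| quadrant angles | 25, 25, 135, 135° | the rig's nominal construction |
| camera aim offsets | ±0.155 pitch | cameras sit over their quadrants, so the plate center is slightly off-center per frame; breaks accidental symmetry in tests |
| noise σ | 2.55 (1% of 8-bit range) | study condition for all stochastic checks |
| vignette strength | 0.05 | mild falloff of the kind visible in real quadrant frames; shape is our choice, not measured |
| background | 0 | the blank tables already carry the real system's ~12-unit floor (background + autofluorescence) inside the tubes, so adding a scene background would double-count it |

Noise is seeded per image (twelve distinct streams per acquisition derived
from one seed); renders are bit-exact reproducible.

**What the generator does not emulate:** lens PSF/defocus, spectral
response, chromatic effects, tube meniscus and edge artifacts, illumination
gradients other than the radial vignette, hot pixels, and any temporal
drift. Passing the synthetic round trip therefore demonstrates that the
*geometry and arithmetic* of the chain are correct and unbiased at realistic
noise — not that detection on a physical rig will meet the same margins.

### The `table3` reference preset

Only nine summary statistics of the reference 25-tube measurement are
published (mean/min/max of FAM, DDW, and their per-tube ratio), not the
per-tube values. The preset is one fixed joint table pair satisfying all
nine to <1e−6, constructed by a constrained solve
(`scripts/build_preset_tables.py`): the four extreme tubes are pinned first
(FAM-min carries the ratio minimum; the DDW-max tube is paired with a high
ratio, because DDW's tight 12.00–14.03 range leaves only ~3.2 units of
total spread and the required FAM-sum covariance must come from somewhere),
then 21 free tubes follow a skewed blank pattern hugging the 12.00 floor
with a rank-1 correction landing the FAM sum exactly. The frozen arrays are
verified by direct recomputation of all nine statistics in the test suite.
Any other feasible table would serve; nothing downstream depends on the
particular solution.

## Calibration

* **Binarization:** Otsu's global threshold — parameter-free and adequate
  for high-contrast mark sheets. Component area gates default to 25 px²
  minimum (speck rejection); radius-derived gates (π(r/2)² … π(2r)²) are
  available when the geometry is known.
* **Centroids** are intensity-weighted (center of gravity), not binary-mask
  centroids.
* **Ordering / axis disambiguation:** a square grid of identical circles is
  4-fold symmetric, so lattice axes cannot be assigned to plate rows vs.
  columns from one mark sheet alone. A per-quadrant prior angle (the rig's
  nominal 25/25/135/135°, overridable) de-rotates the points; rows are then
  split at the four largest gaps in sorted y. The prior needs to be within
  ~7° of truth (beyond that, row bands start to mix); the estimated angle
  itself does not inherit the prior's error.
* **Residuals** are distances to the least-squares uniform similarity
  lattice (complex regression `z ≈ t + a·w`, 4 real parameters); `|a|` is
  the fitted pitch, which registration reuses. A fitted lattice makes "the
  distances between the tubes" well-defined without ground truth.

Measured behavior (test suite): angle error <0.5° over 100 random angles at
up to 2% noise, typically ~0.02°; center recovery <1 px; max lattice
residual <1.5 px at 2% noise.

## Registration

Rotation and cropping use bilinear resampling (`scipy.ndimage`
`map_coordinates`, order 1); integer-aligned crops short-circuit to exact
sub-array extraction. Out-of-frame source pixels are filled with 0 **and
excluded from merging** via validity masks, so frame edges never darken the
composite.

**Merge rule.** Pixel-wise mean over contributing quadrants, where
"contributing" means (a) validly resampled and (b) inside the quadrant's
claimed band — its 3×3 window extended half a pitch beyond the outer tubes.
The standard overlapping windows tile the 5-pitch crop exactly, with the
plate's center row/column claimed by multiple quadrants and averaged
(noise σ shrinks as 1/√k there, verified ≈ σ/2 for 4-way overlap). Restricting
each quadrant to its band is forced by the acquisition model: a quadrant
image carries no signal for tubes outside its window, so an unrestricted
mean would dilute every non-shared tube by the number of cameras. `sum` and
`max` modes and `windows=None` (unrestricted masked mean) are provided for
comparison. Mean preserves the intensity scale; photometry stays in float
throughout, quantization happens only on export.

Default crop: 805 px = 5 × 161 px pitch, covering all 25 ROIs.

## Quantification

* Corner tubes are located from the registration geometry (plate center +
  2 pitches along each axis) and refined by local intensity centroid on the
  bright (FAM) composite; background separation inside the search window
  uses Otsu with a contrast test (the disk fills ~half the window, so a
  median-based background would swallow it). Blank windows fall back to the
  approximate position with a warning. The **same grid** is reused for the
  blank image, so both conditions sample identical pixels per tube.
* The averaging square is placed at the center rounded to the nearest
  pixel; an even side s spans [c−s/2, c+s/2). The 80 px square inside a
  ≥64 px-radius tube tolerates that rounding plus the ≤1.5 px registration
  tolerance by construction.
* **No background subtraction.** The blank's ~12-unit floor is part of the
  reported statistic; the relative gain is the raw per-tube ratio FAM/DDW.
  The published summary table is mutually consistent under this reading
  (55.23/12.27 ≈ 4.50 near the printed mean gain 4.48), whereas a
  "difference over blank" reading is not; we implement the ratio and treat
  the gain summary (mean/min/max) as statistics of the 25 per-tube ratios.

## Numerical and degenerate-input choices

* Ratios are exactly invariant under common exposure scaling up to float
  rounding; tests assert 1e−12 relative.
* `detect_circles` errors below the expected count, keeps the largest
  components (with a warning) above it; constant images report "0 circles".
* Degenerate corner quadrilaterals (zero area) and non-uniform grids
  (adjacent-spacing CV ≥5%) are rejected at `TubeGrid` construction.
* Merged pixels with no contributor are 0; `GainReport` refuses blanks ≤0.
* All randomness flows from explicit integer seeds; pipeline reruns write
  byte-identical reports.

## Problem sizes used in validation

Unit and property tests run on 400 px frames with a 56 px pitch (the full
grid plus aim offsets fits at every angle); the end-to-end acceptance
checks run the full native geometry (1440×1120 frames, 161 px pitch,
805 px composite, 1% noise) — four quadrants × three conditions, rendered,
calibrated, registered and quantified from scratch. Measured end-to-end
recovery at these conditions: FAM/DDW brightness means within ~0.7% of the
generating tables (the vignette accounts for most of it and cancels in the
gain), gain summary within 0.01–0.02 of the generating ratios.

## Known limitations

* Pure rotation+translation model; no distortion correction (see above).
* The vignette model and the aim offsets are plausible inventions, not
  measurements; absolute brightness recovery on real hardware will carry
  whatever shading the real optics add (the ratio statistic is robust to
  any shading shared by both conditions).
* Endpoint quantification only: no amplification-curve fitting, cycle
  series, or melt analysis.
* The angle-axis disambiguation relies on the nominal rig angles; a rig
  assembled outside ±~7° of nominal needs its priors updated in
  `PipelineConfig`.
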