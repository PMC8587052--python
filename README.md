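# quadfluor

Fluorescence quantification for real-time-PCR tube plates imaged by **four
overlapping compact cameras**.

Camera-based qPCR fluorescence readout usually needs one large, expensive
sensor with a wide field of view. An alternative rig replaces it with four
cheap fixed cameras, each looking at one overlapping 3×3 quadrant of a 5×5
tube plate through a green emission filter. The price of that simplification
is image processing: each camera sees the plate rotated (by construction,
~25° for the two upper-quadrant cameras and ~135° for the two lower ones)
and offset, and the four views must be fused into a single registered plate
image before any well can be measured. `quadfluor` implements that whole
chain, plus a synthetic scene renderer with exact ground truth so the chain
can be validated without the hardware.

## Method

1. **Calibration** (`quadfluor.calib`). Each camera photographs a mark sheet
   of 25 fluorescent circles at the tube positions. The image is binarized
   (Otsu), connected bright components are reduced to intensity-weighted
   centroids, ordered into the 5×5 grid, and the camera's rigid alignment is
   estimated: rotation center = the detected center tube **c** = x₂₂, and
   rotation angle θ = the counterclockwise rotation carrying the vector
   **v** = x₀₄ − x₂₂ (center → top-right corner tube) onto the plate
   diagonal (+1, −1)/√2. Residuals come from a least-squares fit of a
   uniform lattice (translation, rotation, spacing) to the 25 centroids.
2. **Registration** (`quadfluor.register`). Each quadrant image is rotated
   by θ about **c** (bilinear), cropped to a common frame centered on **c**,
   and the four crops are merged by a mask-aware pixel-wise mean: each
   quadrant contributes the band around its own 3×3 window, and the shared
   center row/column is averaged over the quadrants that image it, which is
   where the multi-camera SNR gain comes from.
3. **Quantification** (`quadfluor.quantify`). The 25 tube centers are
   reconstructed from the four corner tubes by bilinear interpolation,
   center(i, j) = (1−v)[(1−u)·TL + u·TR] + v[(1−u)·BL + u·BR] with u = j/4,
   v = i/4. Per tube, brightness is the plain mean over an 80 px square
   inside a 161 px ROI (no background subtraction), and the detection
   statistic is the per-tube **relative gain** g᎐ᵢⱼ = FAMᵢⱼ / DDWᵢⱼ, the
   ratio of fluorophore brightness (FAM, a reference dye matching fully
   amplified DNA) to the blank (double-distilled water).

The synthetic generator (`quadfluor.synth`) renders all of this with
anti-aliased disks, per-quadrant rotations, vignetting, and seeded Gaussian
sensor noise; its `table3` preset is a frozen FAM/DDW table pair whose nine
summary statistics match the reference device's published values
(FAM 55.23/34.48/85.11, DDW 12.27/12.00/14.03, gain 4.48/2.84/6.37).

## Worked example

```python
from quadfluor import PipelineConfig, run_pipeline, render_quadrant_set, table3_preset
from quadfluor.synth import SceneConfig

fam, ddw = table3_preset()
scenes = render_quadrant_set(fam, ddw, base_config=SceneConfig(noise_sd=2.55), seed=42)
result = run_pipeline(PipelineConfig(), scenes.mark_images,
                      scenes.fam_images, scenes.ddw_images)
for qid, cal in result.calibrations.items():
    print(f"quadrant {qid}: angle {cal.rotation_angle:6.2f} deg, "
          f"max residual {cal.max_residual:.2f} px")
print(f"FAM mean brightness {result.fam_table.mean:.2f}")
print(f"DDW mean brightness {result.ddw_table.mean:.2f}")
print(f"relative gain mean {result.gain.mean:.2f} "
      f"min {result.gain.min:.2f} max {result.gain.max:.2f}")
```

prints

```
quadrant 1: angle  25.00 deg, max residual 0.02 px
quadrant 2: angle  25.00 deg, max residual 0.01 px
quadrant 3: angle 135.00 deg, max residual 0.02 px
quadrant 4: angle 135.00 deg, max residual 0.01 px
FAM mean brightness 54.89
DDW mean brightness 12.18
relative gain mean 4.48 min 2.86 max 6.40
```

The calibrated angles recover the rig's nominal 25°/135° rotations to
hundredths of a degree at 1% sensor noise; the extracted brightness means
sit within ~0.7% of the generating tables (the small shortfall is the
rendered vignette, which cancels in the gain because both conditions share
it); and every well's gain clears the blank by at least ×2.8 — the
all-wells detection margin of the device.

The same chain is available from the shell:

```sh
quadfluor synth --preset table3 --out scene/ --seed 42 --noise-sd 2.55
quadfluor run --indir scene/ --out result/     # writes report.csv, merged TIFFs, calib JSONs
```

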