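"""Image/channel handling, configuration and the end-to-end pipeline.

`run_pipeline` chains the full chain the device performs per measurement:
per-quadrant mark-sheet calibration, registration of the fluorophore (FAM)
and blank (DDW) quadrant sets with the *same* calibrations, tube-grid
construction on the FAM composite, brightness extraction for both
conditions with the identical grid, and the per-tube relative gain.

All photometry is carried in floating point; 8-bit conversion happens only
in :func:`scale_for_display` and on PNG export.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import calib as _calib
from . import quantify as _quantify
from . import register as _register
from .calib import CalibrationResult
from .quantify import BrightnessTable, GainReport, TubeGrid

logger = logging.getLogger("quadfluor")

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "channel_select",
    "scale_for_display",
    "read_image",
    "write_image",
    "report_frame",
    "run_pipeline",
]

#: ITU-R BT.601 luma weights, the standard broadcast luminance weighting.
_LUMA = np.array([0.299, 0.587, 0.114])

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end processing parameters.

    ``quadrant_angles_prior`` seeds the grid-axis disambiguation per
    quadrant id 1-4 (the rig's nominal 25/25/135/135 construction).  The
    ROI geometry follows the device: a 161 px region per tube with an 80 px
    averaging square.  ``display_gain_ddw`` is the visualization-only
    brightness boost applied to blank images on export.
    """

    quadrant_angles_prior: tuple[float, float, float, float] = (25.0, 25.0, 135.0, 135.0)
    roi_size: int = 161
    avg_size: int = 80
    crop_size: int = 805
    merge_mode: str = "mean"
    channel: str = "green"
    display_gain_ddw: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.avg_size < self.roi_size:
            raise ValueError("need 0 < avg_size < roi_size")
        if self.display_gain_ddw <= 0:
            raise ValueError("display_gain_ddw must be positive")
        if self.merge_mode not in ("mean", "sum", "max"):
            raise ValueError(f"unknown merge_mode {self.merge_mode!r}")
        if self.channel not in ("green", "luminance", "red", "blue"):
            raise ValueError(f"unknown channel {self.channel!r}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["quadrant_angles_prior"] = tuple(d["quadrant_angles_prior"])
        return cls(**d)


@dataclass
class PipelineResult:
    calibrations: dict[int, CalibrationResult]
    merged_fam: "_register.MergedImage"
    merged_ddw: "_register.MergedImage"
    grid: TubeGrid
    fam_table: BrightnessTable
    ddw_table: BrightnessTable
    gain: GainReport


def channel_select(image: np.ndarray, channel: str = "green") -> np.ndarray:
    """Reduce an RGB or grayscale image to one floating-point channel.

    The default is the green plane, matching a green fluorescence emission
    band; ``luminance`` applies the BT.601 weighting.  Grayscale input
    passes through unchanged (as float).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[-1] == 3:
        if channel == "luminance":
            return img @ _LUMA
        try:
            return img[..., _CHANNEL_INDEX[channel]]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}") from None
    raise ValueError(f"unsupported image shape {img.shape}; need HxW or HxWx3")


def scale_for_display(image: np.ndarray, factor: float) -> np.ndarray:
    """Brighten for visualization only: multiply, clip to 8 bit, round.

    Rounding is half away from zero.  The result never feeds quantification.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    y = np.clip(np.asarray(image, dtype=float) * factor, 0.0, 255.0)
    return np.floor(y + 0.5).astype(np.uint8)


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a float array (2-D or HxWx3)."""
    arr = iio.imread(path)
    return np.asarray(arr, dtype=float)


def write_image(path, image: np.ndarray, bit_depth: int = 8) -> None:
    """Write an image, quantizing to 8-bit PNG or 16-bit TIFF by suffix/depth."""
    path = Path(path)
    img = np.asarray(image, dtype=float)
    if path.suffix.lower() in (".tif", ".tiff"):
        if bit_depth == 16:
            tifffile.imwrite(path, np.clip(np.rint(img), 0, 65535).astype(np.uint16))
        else:
            tifffile.imwrite(path, img.astype(np.float32))
    else:
        iio.imwrite(path, np.clip(np.rint(img), 0, 255).astype(np.uint8))


def report_frame(fam: BrightnessTable, ddw: BrightnessTable,
                 gain: GainReport) -> pd.DataFrame:
    """Tidy per-tube report: one row per tube with fam, ddw and gain."""
    rows = []
    for i in range(5):
        for j in range(5):
            rows.append({"row": i, "col": j,
                         "fam": fam.values[i, j],
                         "ddw": ddw.values[i, j],
                         "gain": gain.gains[i, j]})
    return pd.DataFrame(rows)


def _approx_corner_positions(crop_size: int, spacing: float) -> np.ndarray:
    """Corner-tube positions implied by the registration geometry.

    After registration the plate center tube sits at the crop center and
    the grid is axis-aligned with the calibrated pitch, so the corners lie
    two pitches out along each axis.  Order: TL, TR, BL, BR.
    """
    c = (crop_size - 1) / 2.0
    s = 2.0 * spacing
    return np.array([[c - s, c - s], [c + s, c - s],
                     [c - s, c + s], [c + s, c + s]])


def run_pipeline(config: PipelineConfig, marksheet_images, fam_images,
                 ddw_images, outdir=None) -> PipelineResult:
    """Run calibration, registration and quantification end to end.

    The three image collections are dicts keyed by quadrant id (1-4) or
    sequences in id order.  RGB inputs are reduced with the configured
    channel.  When ``outdir`` is given, calibration JSONs, merged TIFFs,
    display PNGs and the per-tube CSV report are written there.
    """
    def _as_dict(images):
        if isinstance(images, dict):
            return {int(q): channel_select(im, config.channel)
                    for q, im in images.items()}
        return {q + 1: channel_select(im, config.channel)
                for q, im in enumerate(images)}

    marks = _as_dict(marksheet_images)
    fams = _as_dict(fam_images)
    ddws = _as_dict(ddw_images)
    if not (marks.keys() == fams.keys() == ddws.keys()):
        raise ValueError("mark-sheet, FAM and DDW sets must cover the same quadrants")

    logger.info("pipeline config: roi_size=%d avg_size=%d crop_size=%d "
                "merge_mode=%s channel=%s angle priors=%s",
                config.roi_size, config.avg_size, config.crop_size,
                config.merge_mode, config.channel, config.quadrant_angles_prior)

    calibrations: dict[int, CalibrationResult] = {}
    for qid in sorted(marks):
        prior = config.quadrant_angles_prior[qid - 1]
        try:
            cal = _calib.calibrate_quadrant(marks[qid], qid, angle_prior=prior)
        except Exception as exc:
            raise RuntimeError(f"calibration failed for quadrant {qid}: {exc}") from exc
        logger.info("quadrant %d: angle=%.3f deg center=(%.2f, %.2f) "
                    "spacing=%.2f px mean residual=%.3f px max=%.3f px",
                    qid, cal.rotation_angle, *cal.rotation_center,
                    cal.grid_spacing, cal.mean_residual, cal.max_residual)
        calibrations[qid] = cal

    cals = [calibrations[q] for q in sorted(calibrations)]
    try:
        merged_fam = _register.register_set(fams, cals, config.crop_size,
                                            mode=config.merge_mode)
        merged_ddw = _register.register_set(ddws, cals, config.crop_size,
                                            mode=config.merge_mode)
    except Exception as exc:
        raise RuntimeError(f"registration failed: {exc}") from exc

    spacing = float(np.mean([c.grid_spacing for c in cals]))
    approx = _approx_corner_positions(config.crop_size, spacing)
    # corner refinement runs on the bright (FAM) composite; the identical
    # grid is then reused for the blank so both conditions sample the same
    # pixels per tube
    radius = min(int(config.roi_size // 2),
                 int(spacing / 2) - 1)
    try:
        corners = _quantify.corner_centers_from_merged(
            merged_fam.pixels, approx, search_radius=radius)
        grid = _quantify.interpolate_centers(corners, config.roi_size,
                                             config.avg_size)
        fam_table = _quantify.extract_brightness(merged_fam.pixels, grid, "FAM")
        ddw_table = _quantify.extract_brightness(merged_ddw.pixels, grid, "DDW")
        gain = _quantify.relative_gain(fam_table, ddw_table)
    except Exception as exc:
        raise RuntimeError(f"quantification failed: {exc}") from exc
    logger.info("gain: mean=%.3f min=%.3f max=%.3f",
                gain.mean, gain.min, gain.max)

    result = PipelineResult(calibrations, merged_fam, merged_ddw, grid,
                            fam_table, ddw_table, gain)
    if outdir is not None:
        _write_artifacts(config, result, Path(outdir))
    return result


def _write_artifacts(config: PipelineConfig, result: PipelineResult,
                     outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "pipeline_config.json").write_text(config.to_json())
    for qid, cal in result.calibrations.items():
        (outdir / f"calibration_q{qid}.json").write_text(cal.to_json())
    write_image(outdir / "merged_fam.tiff", result.merged_fam.pixels, bit_depth=16)
    write_image(outdir / "merged_ddw.tiff", result.merged_ddw.pixels, bit_depth=16)
    write_image(outdir / "merged_fam.png", result.merged_fam.pixels)
    write_image(outdir / "merged_ddw_display.png",
                scale_for_display(result.merged_ddw.pixels,
                                  config.display_gain_ddw))
    frame = report_frame(result.fam_table, result.ddw_table, result.gain)
    frame.to_csv(outdir / "report.csv", index=False, float_format="%.6f")
    summary = {
        "fam_mean": result.fam_table.mean,
        "ddw_mean": result.ddw_table.mean,
        "gain_mean": result.gain.mean,
        "gain_min": result.gain.min,
        "gain_max": result.gain.max,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
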