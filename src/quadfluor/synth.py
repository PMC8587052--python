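"""Synthetic four-camera plate scenes with known ground truth.

The physical rig images a 5 x 5 array of PCR tubes with four fixed compact
cameras, each emphasising one overlapping 3 x 3 quadrant of the plate.  This
module renders the three image kinds that rig produces — the fluorescent
mark sheet used for calibration, and tube plates filled with a fluorophore
(FAM) or with a blank (double-distilled water, DDW) — as raster images with
exactly known geometry and per-tube intensities, so the whole downstream
chain (calibration, registration, quantification) can be validated without
hardware.

Rendered tubes are anti-aliased filled disks added on top of a uniform
background, optionally attenuated by a radial vignette, corrupted by
additive Gaussian sensor noise, then clipped and quantized to the sensor
bit depth.  All randomness is driven by the ``seed`` in :class:`SceneConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    DEFAULT_ANGLE_PRIORS,
    QUADRANT_WINDOWS,
    grid_offsets,
    rotate_points,
)

__all__ = [
    "SceneConfig",
    "IntensityTable",
    "QuadrantSet",
    "RenderError",
    "render_mark_sheet",
    "render_tube_quadrant",
    "render_quadrant_set",
    "table3_preset",
]


class RenderError(ValueError):
    """A scene configuration cannot be rendered (e.g. circles out of frame)."""


@dataclass(frozen=True)
class SceneConfig:
    """Parametric description of one camera's view of the plate.

    ``rotation_angle`` follows the package-wide convention (see
    :mod:`quadfluor.geometry`): it is the counterclockwise correction, in
    degrees, that aligns the imaged grid with the plate axes.  The renderer
    therefore places the grid rotated *clockwise* by this amount, so that a
    downstream CCW rotation by ``rotation_angle`` registers it.

    Intensities are in pixel-value units of the configured bit depth; disk
    amplitudes add on top of ``background_level``.
    """

    image_width: int = 1440
    image_height: int = 1120
    rotation_center: tuple[float, float] = (719.5, 559.5)
    rotation_angle: float = 25.0
    grid_spacing: float = 161.0
    tube_radius: float = 64.0
    visible_rows: tuple[int, ...] = (0, 1, 2)
    visible_cols: tuple[int, ...] = (2, 3, 4)
    background_level: float = 0.0
    noise_sd: float = 2.55
    vignette_strength: float = 0.05
    bit_depth: int = 8
    seed: int = 0
    mark_level: float = 200.0

    def __post_init__(self):
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.grid_spacing <= 2 * self.tube_radius:
            raise ValueError("grid_spacing must exceed the tube diameter")
        for name, idx in (("visible_rows", self.visible_rows),
                          ("visible_cols", self.visible_cols)):
            idx = tuple(idx)
            if len(idx) != 3 or list(idx) != list(range(idx[0], idx[0] + 3)) \
                    or idx[0] < 0 or idx[-1] > 4:
                raise ValueError(
                    f"{name} must be 3 consecutive indices in 0..4, got {idx}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError("vignette_strength must be in [0, 1)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def max_value(self) -> float:
        return float(2 ** self.bit_depth - 1)

    def ground_truth_centers(self) -> np.ndarray:
        """Exact sub-pixel tube centers in this camera's frame, ``(5, 5, 2)``.

        The grid appears rotated clockwise-as-displayed by ``rotation_angle``
        about ``rotation_center`` (so that rotating the image CCW by that
        angle aligns it with the plate axes).
        """
        pts = grid_offsets(self.grid_spacing)
        pts[..., 0] += self.rotation_center[0]
        pts[..., 1] += self.rotation_center[1]
        return rotate_points(pts, self.rotation_center, -self.rotation_angle)


@dataclass(frozen=True)
class IntensityTable:
    """Per-tube mean signal amplitude for one condition, 5 x 5."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (5, 5):
            raise ValueError(f"intensity table must be 5x5, got {v.shape}")
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "values", v)


def _disk_coverage(shape, center, radius):
    """Anti-aliased coverage of a disk, returned as (row slice, col slice, alpha).

    Boundary pixels get fractional weight ``clip(radius + 0.5 - d, 0, 1)``,
    a linear approximation of pixel-area coverage adequate for sub-pixel
    centroid work.
    """
    h, w = shape
    cx, cy = center
    x0 = int(np.floor(cx - radius - 1))
    x1 = int(np.ceil(cx + radius + 1)) + 1
    y0 = int(np.floor(cy - radius - 1))
    y1 = int(np.ceil(cy + radius + 1)) + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0))
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    d = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    alpha = np.clip(radius + 0.5 - d, 0.0, 1.0)
    return slice(y0c, y1c), slice(x0c, x1c), alpha


def _render(config: SceneConfig, amplitudes: np.ndarray,
            mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Render disks with given amplitudes where ``mask`` is True."""
    h, w = config.image_height, config.image_width
    centers = config.ground_truth_centers()
    img = np.full((h, w), float(config.background_level))
    r = config.tube_radius
    for i in range(5):
        for j in range(5):
            if not mask[i, j]:
                continue
            cx, cy = centers[i, j]
            if not (r <= cx <= w - 1 - r and r <= cy <= h - 1 - r):
                raise RenderError(
                    f"tube (row={i}, col={j}) at ({cx:.1f}, {cy:.1f}) falls "
                    f"outside the {w}x{h} frame")
            ysl, xsl, alpha = _disk_coverage((h, w), (cx, cy), r)
            img[ysl, xsl] += amplitudes[i, j] * alpha
    if config.vignette_strength > 0:
        icx, icy = (w - 1) / 2.0, (h - 1) / 2.0
        rmax = np.hypot(icx + 0.5, icy + 0.5)
        yy, xx = np.mgrid[0:h, 0:w]
        rr2 = ((xx - icx) ** 2 + (yy - icy) ** 2) / rmax**2
        img *= 1.0 - config.vignette_strength * rr2
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    # sensor quantization: clip to bit depth and round to integer codes,
    # kept in float64 for downstream processing
    img = np.rint(np.clip(img, 0.0, config.max_value))
    return img, centers


def render_mark_sheet(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render the calibration mark sheet: all 25 circles at ``mark_level``.

    The mark sheet is attached to the well plate bottom and every camera
    photographs the full 25-circle grid, regardless of ``visible_rows`` /
    ``visible_cols`` (those only restrict tube renders).

    Returns ``(image, centers)`` where ``centers`` is the ``(5, 5, 2)``
    ground-truth sub-pixel center array.
    """
    amp = np.full((5, 5), float(config.mark_level))
    return _render(config, amp, np.ones((5, 5), dtype=bool))


def render_tube_quadrant(config: SceneConfig, intensities: IntensityTable
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Render the tubes this camera sees, each disk at its table amplitude.

    Only tubes with ``(row, col)`` in ``visible_rows x visible_cols`` are
    drawn; the returned ``(5, 5, 2)`` ground truth covers the full grid
    geometry (use the config's visibility to select the rendered subset).
    """
    mask = np.zeros((5, 5), dtype=bool)
    mask[np.ix_(config.visible_rows, config.visible_cols)] = True
    return _render(config, intensities.values, mask)


@dataclass
class QuadrantSet:
    """Twelve rendered images plus full ground truth for one plate scene."""

    mark_images: dict[int, np.ndarray]
    fam_images: dict[int, np.ndarray]
    ddw_images: dict[int, np.ndarray]
    configs: dict[int, SceneConfig]
    centers: dict[int, np.ndarray]          # (5,5,2) per quadrant frame
    fam: IntensityTable
    ddw: IntensityTable

    @property
    def angles(self) -> dict[int, float]:
        return {q: c.rotation_angle for q, c in self.configs.items()}


#: Camera aim offsets, one per quadrant id, in units of the grid pitch.
#: Each camera sits over its own quadrant, so the plate center is slightly
#: off-center in its frame; the offsets keep the scenes from being trivially
#: symmetric while the full mark-sheet grid still fits in the frame.
_CENTER_OFFSETS = {1: (-0.155, 0.155), 2: (0.155, 0.155),
                   3: (0.155, -0.155), 4: (-0.155, -0.155)}


def render_quadrant_set(fam: IntensityTable, ddw: IntensityTable, *,
                        base_config: SceneConfig | None = None,
                        angles: dict[int, float] | None = None,
                        windows: dict[int, tuple] | None = None,
                        seed: int = 0) -> QuadrantSet:
    """Render the full four-camera acquisition: mark sheets, FAM and DDW.

    Per-quadrant rotation angles default to the rig's nominal construction
    (25 degrees for quadrants 1-2, 135 for quadrants 3-4) and the visible
    3 x 3 windows default to the standard overlapping quadrant layout, whose
    union covers all 25 tubes with the center tube seen by all four cameras.
    Geometry is identical across the three conditions of each quadrant; each
    of the twelve images gets its own noise stream derived from ``seed``.
    """
    base = base_config if base_config is not None else SceneConfig()
    angles = dict(DEFAULT_ANGLE_PRIORS if angles is None else angles)
    windows = dict(QUADRANT_WINDOWS if windows is None else windows)
    covered = np.zeros((5, 5), dtype=bool)
    for rows, cols in windows.values():
        covered[np.ix_(rows, cols)] = True
    if not covered.all():
        missing = np.argwhere(~covered).tolist()
        raise ValueError(f"quadrant windows do not cover tubes {missing}")

    icx = (base.image_width - 1) / 2.0
    icy = (base.image_height - 1) / 2.0
    mark, famimg, ddwimg, configs, centers = {}, {}, {}, {}, {}
    for k, qid in enumerate(sorted(windows)):
        off = _CENTER_OFFSETS.get(qid, (0.0, 0.0))
        cfg = replace(
            base,
            rotation_center=(icx + off[0] * base.grid_spacing,
                             icy + off[1] * base.grid_spacing),
            rotation_angle=angles[qid],
            visible_rows=tuple(windows[qid][0]),
            visible_cols=tuple(windows[qid][1]),
        )
        mark[qid], centers[qid] = render_mark_sheet(
            replace(cfg, seed=seed * 16 + 3 * k))
        famimg[qid], _ = render_tube_quadrant(
            replace(cfg, seed=seed * 16 + 3 * k + 1), fam)
        ddwimg[qid], _ = render_tube_quadrant(
            replace(cfg, seed=seed * 16 + 3 * k + 2), ddw)
        configs[qid] = cfg
    return QuadrantSet(mark, famimg, ddwimg, configs, centers, fam, ddw)


# ---------------------------------------------------------------------------
# Frozen reference intensity tables
#
# A fixed pair of 5x5 FAM/DDW tables constructed (by constrained solve, see
# docs/methods.md) to jointly reproduce the reference device statistics:
#   FAM  mean 55.23  min 34.48  max 85.11
#   DDW  mean 12.27  min 12.00  max 14.03
#   per-tube FAM/DDW ratio  mean 4.48  min 2.84  max 6.37
# All nine statistics hold to better than 1e-6.
# ---------------------------------------------------------------------------

_TABLE3_FAM = np.array([
    [54.480996, 60.600667, 42.632785, 40.052008, 34.480000],
    [49.543206, 64.282382, 57.432884, 63.177437, 44.758099],
    [39.504962, 82.777000, 64.099488, 64.302333, 36.000000],
    [47.757414, 62.103434, 51.931795, 38.398377, 63.834549],
    [51.761601, 85.110000, 57.017889, 63.886475, 60.824218],
])

_TABLE3_DDW = np.array([
    [12.064918, 12.046370, 12.083466, 12.111288, 12.140845],
    [12.032459, 12.306043, 12.102014, 12.185481, 12.074192],
    [12.055644, 14.030000, 12.482249, 12.389509, 12.000000],
    [12.027822, 12.148384, 12.092740, 12.023185, 12.241125],
    [12.018548, 13.361068, 12.037096, 12.574990, 12.120562],
])


def table3_preset() -> tuple[IntensityTable, IntensityTable]:
    """The frozen FAM/DDW per-tube brightness pair used as reference scene."""
    return (IntensityTable(_TABLE3_FAM.copy(), "FAM"),
            IntensityTable(_TABLE3_DDW.copy(), "DDW"))
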