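"""Registration: rotate each quadrant image, crop to a common frame, merge.

Each camera image is rotated counterclockwise by its calibrated angle about
its calibrated rotation center (the plate center tube), which aligns the
tube grid with the plate axes.  A fixed-size window centered on the rotation
center is then resampled from each rotated image, so the plate center tube
lands exactly at the geometric center of every crop, and the four crops are
merged pixel-wise into one plate image.

The default merge is a mask-aware mean: each quadrant contributes only the
pixels it validly imaged (resampled from inside its original frame) and, by
default, only the region around its own 3 x 3 tube window.  Where windows
overlap — the plate's center row and column — contributing quadrants are
averaged, which is what recovers signal-to-noise in the weakly illuminated
shared regions; elsewhere each tube comes from the single camera that
emphasises it.  All photometric processing is floating point; quantization
happens only on image export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .geometry import QUADRANT_WINDOWS, rotate_points

__all__ = [
    "MergedImage",
    "rotate_image",
    "crop_centered",
    "merge_quadrants",
    "register_set",
]

#: Default crop: five ROI pitches of 161 px, covering the full 5 x 5 grid.
DEFAULT_CROP_SIZE = 805

_VALID_EPS = 1e-6


@dataclass
class MergedImage:
    """A registered plate image assembled from quadrant crops.

    ``plate_center`` is the sub-pixel position of the plate center tube in
    merged coordinates — the geometric center ``((w-1)/2, (h-1)/2)`` of the
    crop by construction.  ``weight`` counts how many quadrants contributed
    at each pixel.
    """

    pixels: np.ndarray
    provenance: list[int]
    crop_size: tuple[int, int]
    plate_center: tuple[float, float]
    weight: np.ndarray | None = None

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("provenance must be non-empty")


def _resample(image: np.ndarray, xs: np.ndarray, ys: np.ndarray,
              return_mask: bool):
    """Bilinear sample at (xs, ys); mask marks samples fully inside the frame."""
    out = ndi.map_coordinates(image, [ys, xs], order=1, mode="constant", cval=0.0)
    if not return_mask:
        return out
    h, w = image.shape
    mask = ((xs >= -_VALID_EPS) & (xs <= w - 1 + _VALID_EPS)
            & (ys >= -_VALID_EPS) & (ys <= h - 1 + _VALID_EPS))
    return out, mask


def rotate_image(image: np.ndarray, center, angle: float,
                 return_mask: bool = False):
    """Rotate image content counterclockwise (as displayed) about ``center``.

    Bilinear resampling, output frame equal to the input frame, out-of-frame
    source pixels filled with 0.  With ``return_mask=True`` also returns the
    boolean validity mask of pixels resampled from inside the source frame.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("rotate_image expects a 2-D image")
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    h, w = img.shape
    if not (0 <= center[0] <= w - 1 and 0 <= center[1] <= h - 1):
        raise ValueError("rotation center must lie inside the image")
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # output pixel o shows the source point that the rotation carries onto o
    src = rotate_points(np.stack([xx, yy], axis=-1), center, -angle)
    return _resample(img, src[..., 0], src[..., 1], return_mask)


def crop_centered(image: np.ndarray, center, size,
                  return_mask: bool = False):
    """Extract a ``w x h`` window whose geometric center is ``center``.

    ``size`` is ``(w, h)`` or a single square side.  For integer centers the
    result is a bit-exact sub-array; sub-pixel centers are resolved by
    bilinear resampling so the requested point lands exactly on the crop
    center ``((w-1)/2, (h-1)/2)``.  The window must lie within the frame.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("crop_centered expects a 2-D image")
    if np.isscalar(size):
        size = (int(size), int(size))
    w, h = int(size[0]), int(size[1])
    if w <= 0 or h <= 0:
        raise ValueError("crop size must be positive")
    H, W = img.shape
    cx, cy = float(center[0]), float(center[1])
    x0 = cx - (w - 1) / 2.0
    y0 = cy - (h - 1) / 2.0
    over = {
        "left": max(0.0, -x0), "top": max(0.0, -y0),
        "right": max(0.0, x0 + w - 1 - (W - 1)),
        "bottom": max(0.0, y0 + h - 1 - (H - 1)),
    }
    if max(over.values()) > _VALID_EPS:
        bad = {k: round(v, 2) for k, v in over.items() if v > _VALID_EPS}
        raise ValueError(f"crop window exceeds the image frame by {bad} px")
    if abs(x0 - round(x0)) < _VALID_EPS and abs(y0 - round(y0)) < _VALID_EPS:
        i0, j0 = int(round(y0)), int(round(x0))
        out = img[i0:i0 + h, j0:j0 + w].copy()
        if return_mask:
            return out, np.ones((h, w), dtype=bool)
        return out
    xs = x0 + np.arange(w)
    ys = y0 + np.arange(h)
    xg, yg = np.meshgrid(xs, ys)
    return _resample(img, xg, yg, return_mask)


def merge_quadrants(images, mode: str = "mean", masks=None,
                    provenance=None) -> MergedImage:
    """Merge aligned same-size images pixel-wise.

    ``mode`` is ``mean`` (default; mask-aware average of contributing
    images), ``sum`` or ``max``.  ``masks``, if given, are per-image boolean
    arrays marking pixels that actually carry data; masked-out pixels do not
    contribute, so rotation fill and non-window regions cannot darken the
    composite.  Output stays floating point and unclipped.
    """
    imgs = [np.asarray(im, dtype=float) for im in images]
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("all images to merge must share the same shape")
    if masks is None:
        wts = [np.ones(shape) for _ in imgs]
    else:
        wts = [np.asarray(m, dtype=float) for m in masks]
        if any(m.shape != shape for m in wts):
            raise ValueError("masks must match image shape")
    wsum = np.sum(wts, axis=0)
    if mode == "mean":
        num = np.sum([im * m for im, m in zip(imgs, wts)], axis=0)
        with np.errstate(invalid="ignore"):
            out = np.where(wsum > 0, num / np.maximum(wsum, 1e-30), 0.0)
    elif mode == "sum":
        out = np.sum([im * m for im, m in zip(imgs, wts)], axis=0)
    elif mode == "max":
        stack = np.stack([np.where(m > 0, im, -np.inf)
                          for im, m in zip(imgs, wts)])
        out = stack.max(axis=0)
        out[~np.isfinite(out)] = 0.0
    else:
        raise ValueError(f"unknown merge mode {mode!r}")
    h, w = shape
    prov = list(provenance) if provenance is not None else list(range(len(imgs)))
    return MergedImage(out, prov, (w, h), ((w - 1) / 2.0, (h - 1) / 2.0),
                       weight=wsum)


def _window_mask(shape, spacing, rows, cols) -> np.ndarray:
    """Region of the merged frame claimed by a quadrant's tube window.

    Each quadrant claims the band of rows/columns it images, extended half a
    pitch beyond its outer tubes; the standard overlapping windows then tile
    the crop, with the shared center row/column claimed by several quadrants.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    eps = 1e-9
    ylo = cy + (min(rows) - 2.5) * spacing - eps
    yhi = cy + (max(rows) - 1.5) * spacing + eps
    xlo = cx + (min(cols) - 2.5) * spacing - eps
    xhi = cx + (max(cols) - 1.5) * spacing + eps
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx >= xlo) & (xx <= xhi) & (yy >= ylo) & (yy <= yhi)


def register_set(images, calibrations, crop_size: int = DEFAULT_CROP_SIZE,
                 mode: str = "mean", windows=QUADRANT_WINDOWS) -> MergedImage:
    """Rotate, crop and merge a set of quadrant images into one plate image.

    ``images`` and ``calibrations`` are matched sequences (or dicts keyed by
    quadrant id).  ``windows`` maps quadrant id to its (rows, cols) tube
    window and restricts each quadrant's contribution to the region it
    images; pass ``windows=None`` to let every quadrant contribute
    everywhere (plain masked mean of the aligned crops).
    """
    if isinstance(images, dict):
        pairs = [(images[c.quadrant_id], c) for c in calibrations]
    else:
        pairs = list(zip(images, calibrations))
    qids = [c.quadrant_id for _, c in pairs]
    if len(set(qids)) != len(qids):
        raise ValueError(f"duplicate quadrant ids in calibrations: {qids}")
    crops, masks = [], []
    for img, cal in pairs:
        rot, valid = rotate_image(img, cal.rotation_center,
                                  cal.rotation_angle, return_mask=True)
        crop, inframe = crop_centered(rot, cal.rotation_center, crop_size,
                                      return_mask=True)
        vmask = crop_centered(valid.astype(float), cal.rotation_center,
                              crop_size) >= 1.0 - 1e-9
        mask = vmask & inframe
        if windows is not None:
            mask &= _window_mask(crop.shape, cal.grid_spacing,
                                 *windows[cal.quadrant_id])
        crops.append(crop)
        masks.append(mask)
    return merge_quadrants(crops, mode=mode, masks=masks, provenance=qids)
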