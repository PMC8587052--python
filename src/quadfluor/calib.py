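"""Mark-sheet calibration: circle detection, grid ordering, rotation estimation.

Each camera photographs a fluorescent mark sheet carrying 25 bright circles
at the tube positions.  Calibration binarizes the image (Otsu), finds
connected bright components, takes their intensity-weighted centroids
("centers of gravity"), orders them into the 5 x 5 plate grid, and derives
the rigid transform aligning this camera to the plate frame:

* the rotation center is the detected center tube (plate row 2, col 2);
* the rotation angle is the counterclockwise rotation carrying the vector
  from the center tube to the top-right corner tube (plate row 0, col 4)
  onto its ideal plate-frame direction, the up-and-right diagonal.

Because a square grid of identical circles is 4-fold symmetric, the
assignment of lattice axes to plate rows vs. columns is ambiguous by
multiples of 90 degrees; it is resolved with a per-quadrant prior angle
(25 degrees for quadrants 1-2, 135 for 3-4 by rig construction),
overridable by the caller.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .geometry import DEFAULT_ANGLE_PRIORS, displayed_angle, rotate_points, wrap_angle

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "detect_circles",
    "order_grid",
    "estimate_rotation",
    "calibrate_quadrant",
    "validate_against_reference",
    "default_detect_params",
]


class CalibrationError(RuntimeError):
    """Mark-sheet calibration failed (detection, ordering or geometry)."""


@dataclass(frozen=True)
class CalibrationResult:
    """Per-quadrant rigid alignment estimated from one mark-sheet image.

    ``ordered_centers`` is the ``(5, 5, 2)`` array of detected circle
    centers in camera-image coordinates, indexed by plate (row, col) after
    de-rotation (row 0 = top).  ``grid_spacing`` and the residuals come from
    a least-squares fit of a uniform ideal lattice (translation, rotation
    and spacing free) to the 25 detected centers.
    """

    quadrant_id: int
    rotation_center: tuple[float, float]
    rotation_angle: float
    ordered_centers: np.ndarray
    mean_residual: float
    max_residual: float
    grid_spacing: float

    def __post_init__(self):
        oc = np.asarray(self.ordered_centers, dtype=float)
        if oc.shape != (5, 5, 2):
            raise ValueError("ordered_centers must be (5, 5, 2)")
        object.__setattr__(self, "ordered_centers", oc)
        object.__setattr__(self, "rotation_angle", wrap_angle(self.rotation_angle))
        if not np.allclose(self.rotation_center, oc[2, 2]):
            raise ValueError("rotation_center must equal the center tube position")

    def to_json(self) -> str:
        return json.dumps({
            "quadrant_id": self.quadrant_id,
            "rotation_center": list(self.rotation_center),
            "rotation_angle": self.rotation_angle,
            "ordered_centers": self.ordered_centers.tolist(),
            "mean_residual": self.mean_residual,
            "max_residual": self.max_residual,
            "grid_spacing": self.grid_spacing,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationResult":
        d = json.loads(text)
        return cls(
            quadrant_id=int(d["quadrant_id"]),
            rotation_center=tuple(d["rotation_center"]),
            rotation_angle=float(d["rotation_angle"]),
            ordered_centers=np.asarray(d["ordered_centers"], dtype=float),
            mean_residual=float(d["mean_residual"]),
            max_residual=float(d["max_residual"]),
            grid_spacing=float(d["grid_spacing"]),
        )


def default_detect_params(tube_radius: float) -> dict:
    """Area gates for circle detection derived from the nominal tube radius."""
    return {"min_area": np.pi * (0.5 * tube_radius) ** 2,
            "max_area": np.pi * (2.0 * tube_radius) ** 2}


def detect_circles(image: np.ndarray, min_area: float = 25.0,
                   max_area: float = np.inf, expected: int = 25) -> np.ndarray:
    """Detect bright circles and return sub-pixel intensity-weighted centroids.

    The image is binarized with Otsu's global threshold; connected bright
    components with area in ``[min_area, max_area]`` survive.  If more than
    ``expected`` components survive, the ``expected`` largest are kept with
    a warning; fewer is an error.  Centroids are weighted by pixel intensity
    and returned as an ``(n, 2)`` array of ``(x, y)``, sorted by descending
    component area.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_circles expects a single-channel image")
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    try:
        thr = threshold_otsu(img)
    except ValueError:  # constant image
        raise CalibrationError(f"0 circles found (expected {expected})")
    labels, nlab = ndi.label(img > thr)
    if nlab == 0:
        raise CalibrationError(f"0 circles found (expected {expected})")
    areas = ndi.sum_labels(np.ones_like(img), labels, index=np.arange(1, nlab + 1))
    keep = np.flatnonzero((areas >= min_area) & (areas <= max_area)) + 1
    if len(keep) < expected:
        raise CalibrationError(
            f"{len(keep)} circles found (expected {expected})")
    if len(keep) > expected:
        warnings.warn(
            f"{len(keep)} circles found, keeping the {expected} largest",
            stacklevel=2)
    order = np.argsort(areas[keep - 1])[::-1][:expected]
    keep = keep[order]
    com = ndi.center_of_mass(img, labels, index=keep)  # (y, x) pairs
    return np.array([(x, y) for y, x in com])


def order_grid(centroids: np.ndarray, angle_prior: float = 0.0) -> np.ndarray:
    """Order 25 lattice points into the 5 x 5 plate grid.

    The points are de-rotated by ``angle_prior`` (the approximate alignment
    rotation, within ~7 degrees of truth), split into 5 rows at the 4
    largest gaps in sorted y, and each row sorted by x.  Returns the
    original (un-derotated) coordinates as a ``(5, 5, 2)`` array with row 0
    on top and column 0 on the left after de-rotation.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.shape != (25, 2):
        raise ValueError(f"expected 25 points, got shape {pts.shape}")
    pivot = pts.mean(axis=0)
    aligned = rotate_points(pts, pivot, angle_prior)
    ys = aligned[:, 1]
    srt = np.argsort(ys)
    gaps = np.diff(ys[srt])
    cuts = np.sort(np.argsort(gaps)[-4:])
    if not np.array_equal(cuts, [4, 9, 14, 19]):
        raise CalibrationError(
            "points not separable into 5 rows of 5 after de-rotation")
    ordered = np.empty((5, 5, 2))
    for r in range(5):
        row_idx = srt[5 * r:5 * r + 5]
        row_idx = row_idx[np.argsort(aligned[row_idx, 0])]
        ordered[r] = pts[row_idx]
    return ordered


def estimate_rotation(ordered_centers: np.ndarray
                      ) -> tuple[tuple[float, float], float]:
    """Rotation center and angle from an ordered 5 x 5 grid.

    The center is the middle tube (row 2, col 2).  The angle is the
    counterclockwise rotation mapping the vector from the center to the
    top-right corner tube (row 0, col 4) onto the ideal plate-frame
    diagonal ``(+1, -1)/sqrt(2)`` (up-and-right in the y-down frame),
    normalized to ``[0, 360)``.
    """
    oc = np.asarray(ordered_centers, dtype=float)
    if oc.shape != (5, 5, 2):
        raise ValueError("ordered_centers must be (5, 5, 2)")
    center = oc[2, 2]
    v = oc[0, 4] - center
    if np.hypot(*v) < 1e-9:
        raise CalibrationError("degenerate grid: corner coincides with center")
    angle = wrap_angle(45.0 - displayed_angle(v))
    return (float(center[0]), float(center[1])), angle


def _lattice_fit(ordered: np.ndarray) -> tuple[float, float, float]:
    """LSQ fit of a uniform similarity lattice; returns residual stats + spacing.

    The model ``z_ij = t + a * w_ij`` with complex ``z = x + iy`` and
    ``w = (col-2) + i(row-2)`` has 4 real free parameters (translation,
    rotation, spacing) and a closed-form least-squares solution.
    """
    z = ordered[..., 0] + 1j * ordered[..., 1]
    j, i = np.meshgrid(np.arange(5), np.arange(5))
    w = (j - 2) + 1j * (i - 2)
    zc, wc = z - z.mean(), w - w.mean()
    a = np.vdot(wc, zc) / np.vdot(wc, wc)
    resid = np.abs(zc - a * wc)
    return float(resid.mean()), float(resid.max()), float(np.abs(a))


def calibrate_quadrant(mark_sheet_image: np.ndarray, quadrant_id: int,
                       detect_params: dict | None = None,
                       angle_prior: float | None = None) -> CalibrationResult:
    """Full single-quadrant calibration from a mark-sheet image.

    Composes circle detection, grid ordering (using the quadrant's nominal
    angle prior unless overridden) and rotation estimation; residuals are
    distances from the detected centers to the best-fit uniform lattice.
    """
    params = detect_params or {}
    if angle_prior is None:
        angle_prior = DEFAULT_ANGLE_PRIORS.get(quadrant_id, 0.0)
    centroids = detect_circles(mark_sheet_image, **params)
    ordered = order_grid(centroids, angle_prior=angle_prior)
    center, angle = estimate_rotation(ordered)
    mean_res, max_res, spacing = _lattice_fit(ordered)
    return CalibrationResult(
        quadrant_id=quadrant_id,
        rotation_center=center,
        rotation_angle=angle,
        ordered_centers=ordered,
        mean_residual=mean_res,
        max_residual=max_res,
        grid_spacing=spacing,
    )


def validate_against_reference(result: CalibrationResult,
                               reference_centers: np.ndarray) -> np.ndarray:
    """Per-tube distances between calibrated centers and a reference grid.

    ``reference_centers`` is ``(5, 5, 2)`` in the same image frame (e.g.
    centers detected on a fluorescent-tube image, or generator ground
    truth).  Returns the 5 x 5 array of Euclidean distances in pixels.
    """
    ref = np.asarray(reference_centers, dtype=float)
    if ref.shape != (5, 5, 2):
        raise ValueError("reference_centers must be (5, 5, 2)")
    d = result.ordered_centers - ref
    return np.hypot(d[..., 0], d[..., 1])
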