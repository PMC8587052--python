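"""Shared plate/image geometry.

Conventions used throughout the package:

* Pixel coordinates are 0-based, ``x`` rightward (columns), ``y`` downward
  (rows).  Sub-pixel positions are continuous coordinates located at pixel
  centers, so the center of an ``H x W`` image is ``((W-1)/2, (H-1)/2)``.
* Angles are in degrees and are *counterclockwise positive as displayed*,
  i.e. in the y-down raster frame a +90 degree rotation carries the +x
  direction onto the -y (upward on screen) direction.
* A quadrant's ``rotation_angle`` is the counterclockwise rotation that must
  be applied to the camera image to align the tube grid with the plate axes
  (rows horizontal, row 0 on top).  Equivalently, the grid *appears* rotated
  clockwise by that amount in the raw camera frame.
"""

from __future__ import annotations

import numpy as np

#: Tube plate is a fixed 5 x 5 array.
PLATE_ROWS = 5
PLATE_COLS = 5

#: Which 3 x 3 sub-array of the plate each camera emphasises, by quadrant id.
#: Ids follow the mathematical quadrant convention: 1 = top-right of the
#: plate, 2 = top-left, 3 = bottom-left, 4 = bottom-right (y-down display).
QUADRANT_WINDOWS: dict[int, tuple[tuple[int, ...], tuple[int, ...]]] = {
    1: ((0, 1, 2), (2, 3, 4)),
    2: ((0, 1, 2), (0, 1, 2)),
    3: ((2, 3, 4), (0, 1, 2)),
    4: ((2, 3, 4), (2, 3, 4)),
}

#: Nominal alignment rotation per quadrant, from the rig construction:
#: cameras over quadrants 1-2 are mounted so their images need a ~25 degree
#: counterclockwise correction, quadrants 3-4 a ~135 degree one.
DEFAULT_ANGLE_PRIORS: dict[int, float] = {1: 25.0, 2: 25.0, 3: 135.0, 4: 135.0}


def grid_offsets(spacing: float) -> np.ndarray:
    """Unrotated plate-frame offsets of the 25 tube centers.

    Returns a ``(5, 5, 2)`` array of ``(x, y)`` offsets from the plate
    center tube, row 0 on top (negative y), column 0 on the left.
    """
    j, i = np.meshgrid(np.arange(PLATE_COLS), np.arange(PLATE_ROWS))
    return np.stack([(j - 2) * spacing, (i - 2) * spacing], axis=-1).astype(float)


def rotate_points(points: np.ndarray, center, angle_deg: float) -> np.ndarray:
    """Rotate points counterclockwise (as displayed, y-down) about ``center``.

    ``points`` is any ``(..., 2)`` array of ``(x, y)`` coordinates.
    """
    pts = np.asarray(points, dtype=float)
    cx, cy = float(center[0]), float(center[1])
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    dx = pts[..., 0] - cx
    dy = pts[..., 1] - cy
    out = np.empty_like(pts)
    out[..., 0] = cx + dx * c + dy * s
    out[..., 1] = cy - dx * s + dy * c
    return out


def displayed_angle(v) -> float:
    """Angle of vector ``v = (vx, vy)`` in degrees, CCW-as-displayed from +x.

    In the y-down frame a vector pointing up-and-right has a positive angle.
    Result is normalized to ``[0, 360)``.
    """
    vx, vy = float(v[0]), float(v[1])
    return float(np.rad2deg(np.arctan2(-vy, vx)) % 360.0)


def wrap_angle(angle: float) -> float:
    """Normalize an angle in degrees to ``[0, 360)``."""
    return float(np.mod(angle, 360.0))


def angle_difference(a: float, b: float) -> float:
    """Smallest absolute difference between two angles in degrees."""
    d = abs(wrap_angle(a) - wrap_angle(b))
    return min(d, 360.0 - d)
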