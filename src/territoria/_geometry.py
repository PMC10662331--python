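"""Shared angle and coordinate conventions.

Arrays are indexed (row, col) with the origin at the top-left, so image y
grows downward.  Every user-facing angle is expressed in the mathematical
convention instead: degrees counter-clockwise from the +x axis in a y-up
frame, folded to [0, 180) where the quantity is undirected (axis
orientations, axial angles).  The two helpers below are the only places the
flip between conventions happens.
"""

from __future__ import annotations

import numpy as np


def fold_180(angle_deg: float | np.ndarray) -> float | np.ndarray:
    """Fold an angle in degrees onto [0, 180) (undirected line angle)."""
    return np.mod(angle_deg, 180.0)


def vector_angle_deg(dx: float, dy_row: float) -> float:
    """Math-convention angle of an image-space displacement.

    ``dx`` is a column displacement, ``dy_row`` a row displacement
    (positive = downward); the returned angle is CCW from +x in a y-up
    frame, in (-180, 180].
    """
    return float(np.degrees(np.arctan2(-dy_row, dx)))


def mask_orientation_deg(mask: np.ndarray) -> float:
    """Major-axis orientation of a binary mask from second central moments.

    Returns the math-convention angle of the major axis folded to [0, 180).
    For a perfectly isotropic mask the orientation is arbitrary (0 is
    returned).
    """
    rows, cols = np.nonzero(mask)
    u = cols - cols.mean()
    v = -(rows - rows.mean())
    mu20 = float(np.mean(u * u))
    mu02 = float(np.mean(v * v))
    mu11 = float(np.mean(u * v))
    if abs(mu11) < 1e-12 and abs(mu20 - mu02) < 1e-12:
        return 0.0
    ang = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    return float(fold_180(ang))


def axial_angle_deg(vec_angle_deg: float, axis_angle_deg: float) -> float:
    """Angle between an undirected axis line and a direction, in [0, 180).

    Both inputs are math-convention degrees.  The result is the directed
    difference folded to [0, 180): values <= 45 or >= 135 mean the direction
    lies within 45 degrees of the axis line.
    """
    return float(fold_180(vec_angle_deg - axis_angle_deg))


def is_major_parallel(theta_deg: float) -> bool:
    """Classify an axial angle: within 45 degrees of the major-axis line.

    Boundary angles 45 and 135 classify as major-parallel.
    """
    return theta_deg <= 45.0 or theta_deg >= 135.0
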