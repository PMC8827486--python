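"""Grid geometry and angle conventions for the 8x8 electrode array.

Arrays are stored image-style: ``map[row, col]`` with grid coordinate
``(x, y)`` where ``x = col + 1`` (1..8, left to right) and ``y = row + 1``
(1..8, top to bottom).  User-facing azimuths are *visual*: 0 deg points
rightward (+x) and 90 deg points visually up (toward smaller ``y``).
Index-space angles from :func:`numpy.arctan2` therefore carry the opposite
sign in their y component; the helpers below do the bookkeeping once.
"""

from __future__ import annotations

import numpy as np

GRID_N = 8
#: Inter-electrode distance of the Utah array, micrometres.
DEFAULT_PITCH_UM = 400.0

_Y, _X = np.mgrid[1 : GRID_N + 1, 1 : GRID_N + 1]


def grid_coords() -> tuple[np.ndarray, np.ndarray]:
    """Return ``(X, Y)`` coordinate arrays of shape (8, 8), both 1-based."""
    return _X.astype(float), _Y.astype(float)


def visual_unit_vector(azimuth_deg: float) -> tuple[float, float]:
    """Index-space unit vector for a visual azimuth (0 = right, 90 = up)."""
    a = np.deg2rad(azimuth_deg)
    return float(np.cos(a)), float(-np.sin(a))


def index_angle_to_visual_deg(angle_rad: np.ndarray | float) -> np.ndarray | float:
    """Convert an index-space angle (atan2 with y down) to a visual azimuth."""
    return np.rad2deg(-np.asarray(angle_rad)) % 360.0


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(a)))


def circular_mean(angles: np.ndarray, axis=None) -> np.ndarray | float:
    """Circular mean, Arg(sum exp(i*a)), ignoring NaNs."""
    z = np.exp(1j * np.asarray(angles, dtype=float))
    return np.angle(np.nansum(z, axis=axis))


def circular_std(angles: np.ndarray, axis=None) -> np.ndarray | float:
    """Circular standard deviation sqrt(-2 ln R) of the resultant length R."""
    z = np.exp(1j * np.asarray(angles, dtype=float))
    n = np.sum(~np.isnan(np.asarray(angles, dtype=float)), axis=axis)
    r = np.abs(np.nansum(z, axis=axis)) / n
    r = np.clip(r, 1e-12, 1.0)
    return np.sqrt(-2.0 * np.log(r))
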