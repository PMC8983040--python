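"""Circular helpers shared by the geometry and statistics layers.

All azimuths are degrees, counterclockwise-positive in the distal view
(observer at the distal end of the centriole), measured from +x.
"""

from __future__ import annotations

import numpy as np


def normalize_deg(angle):
    """Map angle(s) to [0, 360)."""
    return np.mod(angle, 360.0)


def signed_circ_diff_deg(a, b):
    """Signed difference a - b mapped to [-180, 180)."""
    return (np.asarray(a, dtype=float) - b + 180.0) % 360.0 - 180.0


def circ_dist_deg(a, b):
    """Absolute circular distance in degrees, in [0, 180]."""
    return np.abs(signed_circ_diff_deg(a, b))


def circular_mean_deg(angles, weights=None):
    """Weighted vector-sum circular mean and mean resultant length.

    Returns (mean_deg in [0, 360), R in [0, 1]). When the resultant is
    exactly zero the mean is undefined and NaN is returned for it.
    """
    a = np.deg2rad(np.asarray(angles, dtype=float))
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum <= 0:
        return float("nan"), 0.0
    c = float(np.sum(w * np.cos(a))) / wsum
    s = float(np.sum(w * np.sin(a))) / wsum
    r = float(np.hypot(c, s))
    if r == 0.0:
        return float("nan"), 0.0
    return float(normalize_deg(np.rad2deg(np.arctan2(s, c)))), r


def circular_rms_deg(errors_deg):
    """RMS of signed circular errors (degrees)."""
    e = signed_circ_diff_deg(errors_deg, 0.0)
    return float(np.sqrt(np.mean(e**2)))


def unit_vector_deg(angle_deg):
    """(x, y) unit vector at the given azimuth."""
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def rot_z(deg: float) -> np.ndarray:
    """3x3 rotation about +z by `deg` (counterclockwise in xy)."""
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking the unit vector `axis` onto +z.

    Rotates about the axis perpendicular to both; identity when the vector
    already points along +z, a 180-degree flip about x when along -z.
    """
    v = np.asarray(axis, dtype=float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    u = np.cross(v, z)
    s = np.linalg.norm(u)
    u = u / s
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)
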