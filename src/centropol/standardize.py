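"""Landmark-based standardization of individual centrioles.

The chain mirrors the measurement workflow for rotationally asymmetric
centriolar signals: (1) verticalize the stack so the long axis points to
+z, (2) fit a circle to the triplet-ring landmarks, (3) fix a rotational
reference azimuth (brightest marker region, or an annotated point such as
the basal foot or one end of a C-shaped density), then (4) map the
particle onto a canonical centriole frame by an in-plane similarity
transform plus an affine axial re-framing, resampling trilinearly with a
validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, map_coordinates
from skimage.filters import threshold_otsu

from .angles import circular_mean_deg, normalize_deg
from .errors import (
    DegenerateAxisError,
    DegenerateRingError,
    NoSignalError,
    ParameterError,
)
from .io import CentrioleAnnotation
from .stack import ImageStack


@dataclass
class CanonicalFrame:
    """The fixed grid all particles are resampled onto.

    Lateral: ``lateral_shape`` squared voxels at ``lateral_pitch_nm``
    pre-expansion nm per voxel, ring radius standardized to ``radius_nm``.
    Axial: ``n_planes`` planes spanning the annotated z-frame (proximal at
    plane 0, distal at the last plane).
    """

    radius_nm: float = 115.0
    lateral_shape: int = 96
    lateral_pitch_nm: float = 5.0
    n_planes: int = 64
    axial_pitch_nm: float = 10.0  # used only in "native" axial mode

    @property
    def radius_vox(self) -> float:
        return self.radius_nm / self.lateral_pitch_nm

    @property
    def center(self) -> float:
        return (self.lateral_shape - 1) / 2.0

    def triplet_azimuths(self, n_triplets: int = 9,
                         triplet1_azimuth_deg: float = 0.0) -> np.ndarray:
        spacing = 360.0 / n_triplets
        return normalize_deg(triplet1_azimuth_deg + spacing * np.arange(n_triplets))


@dataclass
class CircleFit:
    center: tuple
    radius: float
    rms_residual: float
    n_points: int


@dataclass
class StandardizationTransform:
    """Similarity transform from verticalized-stack voxels to the canonical frame.

    Lateral forward map (voxel (x, y)):
        ``canonical_xy = scale * R(rotation) * F * xy + translation``
    where F mirrors y for proximal-view particles.  Axial forward map:
    ``z_canonical = axial_scale * z + axial_offset``.  ``pre_rotation`` is
    the 3D rotation that verticalized the raw stack.
    """

    in_plane_rotation_deg: float
    scale: float
    translation: np.ndarray
    axial_scale: float
    axial_offset: float
    mirror: bool = False
    pre_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    landmark_rms_residual: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ParameterError("transform scale must be > 0")
        self.translation = np.asarray(self.translation, dtype=float)

    def matrix2d(self) -> np.ndarray:
        a = np.deg2rad(self.in_plane_rotation_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        F = np.diag([1.0, -1.0]) if self.mirror else np.eye(2)
        return self.scale * R @ F

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Forward-map (n, 2) lateral or (n, 3) full voxel points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        xy = pts[:, :2] @ self.matrix2d().T + self.translation
        if pts.shape[1] == 2:
            return xy
        z = self.axial_scale * pts[:, 2] + self.axial_offset
        return np.column_stack([xy, z])

    @classmethod
    def _from_parts(cls, M, t, az_scale, az_off) -> "StandardizationTransform":
        det = float(np.linalg.det(M))
        mirror = det < 0
        s = float(np.sqrt(abs(det)))
        R = M @ (np.diag([1.0, -1.0]) if mirror else np.eye(2)) / s
        rot = float(np.rad2deg(np.arctan2(R[1, 0], R[0, 0])))
        return cls(in_plane_rotation_deg=rot, scale=s, translation=t,
                   axial_scale=az_scale, axial_offset=az_off, mirror=mirror)

    def inverse(self) -> "StandardizationTransform":
        M = self.matrix2d()
        Minv = np.linalg.inv(M)
        return self._from_parts(Minv, -Minv @ self.translation,
                                1.0 / self.axial_scale,
                                -self.axial_offset / self.axial_scale)

    def compose(self, other: "StandardizationTransform") -> "StandardizationTransform":
        """self after other: (self o other)(p) = self(other(p))."""
        M1, M2 = self.matrix2d(), other.matrix2d()
        return self._from_parts(
            M1 @ M2, M1 @ other.translation + self.translation,
            self.axial_scale * other.axial_scale,
            self.axial_scale * other.axial_offset + self.axial_offset)


@dataclass
class StandardCentriole:
    """One particle resampled onto the canonical grid."""

    volume: np.ndarray  # (C, n_planes, lateral, lateral) float32
    mask: np.ndarray  # (n_planes, lateral, lateral) bool, True where defined
    particle_id: str
    transform: StandardizationTransform
    channel_roles: dict
    canonical: CanonicalFrame


# ---------------------------------------------------------------------------
# long axis
# ---------------------------------------------------------------------------

def estimate_long_axis(stack: ImageStack, channel="wall",
                       z_frame: tuple | None = None,
                       min_anisotropy: float = 1.05) -> np.ndarray:
    """Principal axis of the intensity-weighted second-moment tensor.

    The wall channel is Otsu-thresholded; the principal eigenvector of the
    covariance of above-threshold voxel positions (physical nm) is the
    axis.  Degeneracy is judged on the covariance whitened by the moments
    of a uniform fill of the bounding box, so a structureless volume is
    rejected regardless of box aspect.  The sign points from z_proximal to
    z_distal (toward +z when no frame is given).
    """
    px, pz = stack.require_pitch()
    vol = stack.channel(channel).astype(np.float64)
    if vol.max() <= 0:
        raise DegenerateAxisError("channel is empty")
    thr = threshold_otsu(vol)
    w = np.where(vol >= thr, vol, 0.0)
    if w.sum() <= 0:
        raise DegenerateAxisError("no voxels above threshold")
    zz, yy, xx = np.nonzero(w)
    weights = w[zz, yy, xx]
    coords = np.stack([xx * px, yy * px, zz * pz], axis=1)
    mu = np.average(coords, axis=0, weights=weights)
    d = coords - mu
    C = (d.T * weights) @ d / weights.sum()

    nz, ny, nx = vol.shape
    ext = np.array([nx * px, ny * px, nz * pz])
    D = np.diag(ext**2 / 12.0)
    Dw = np.diag(1.0 / np.sqrt(np.diag(D)))
    W = Dw @ C @ Dw
    ew = np.linalg.eigvalsh(W)
    if np.sqrt(ew[-1] / max(ew[0], 1e-300)) < min_anisotropy:
        raise DegenerateAxisError(
            f"moment tensor isotropic (whitened anisotropy "
            f"{np.sqrt(ew[-1] / max(ew[0], 1e-300)):.3f} < {min_anisotropy})")

    evals, evecs = np.linalg.eigh(C)
    axis = evecs[:, -1]
    if abs(evals[-1] / max(evals[-2], 1e-300)) < 1.0:  # pragma: no cover
        raise DegenerateAxisError("ambiguous principal axis")
    zsign = 1.0
    if z_frame is not None and z_frame[1] < z_frame[0]:
        zsign = -1.0
    if axis[2] * zsign < 0:
        axis = -axis
    elif axis[2] == 0 and axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def verticalize(stack: ImageStack, axis: np.ndarray):
    """Rotate the volume (about its centre, in physical space) so ``axis`` -> +z.

    Returns ``(stack, rotation)`` where ``rotation`` is the applied 3D
    rotation matrix (acting on physical (x, y, z) offsets from the centre).
    An axis already within ~1e-9 rad of +z short-circuits to the input.
    """
    from .angles import rotation_to_z

    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if not np.isfinite(n) or n == 0:
        raise ParameterError("axis must be a nonzero finite vector")
    axis = axis / n
    if axis[2] > 1.0 - 1e-18 or np.allclose(axis, [0, 0, 1], atol=1e-9):
        return stack, np.eye(3)
    px, pz = stack.require_pitch()
    Rv = rotation_to_z(axis)  # p_vert = Rv @ (p - c) + c
    S = np.diag([px, px, pz])
    A = np.linalg.inv(S) @ Rv.T @ S  # inverse map in voxel units (x, y, z)
    M = A[::-1, ::-1]  # reorder to (z, y, x)
    nzyx = np.array(stack.shape_zyx, dtype=float)
    c = (nzyx - 1) / 2.0
    offset = c - M @ c
    out = np.empty_like(stack.voxels, dtype=np.float32)
    for ci in range(stack.n_channels):
        out[ci] = affine_transform(stack.voxels[ci].astype(np.float64), M,
                                   offset=offset, order=1, mode="constant",
                                   cval=0.0).astype(np.float32)
    out = np.clip(out, 0.0, None)
    vert = ImageStack(voxels=out, voxel_pitch_nm=stack.voxel_pitch_nm,
                      voxel_pitch_z_nm=stack.voxel_pitch_z_nm,
                      channel_roles=dict(stack.channel_roles),
                      view_convention=stack.view_convention)
    return vert, Rv


# ---------------------------------------------------------------------------
# ring fit
# ---------------------------------------------------------------------------

def fit_reference_circle(points: np.ndarray) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through >= 3 landmarks."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise DegenerateRingError("need at least 3 points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] == 0 or s[-1] / s[0] < 1e-9:
        raise DegenerateRingError("degenerate ring: points are collinear")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = float(np.sqrt(c + cx**2 + cy**2))
    resid = np.hypot(x - cx, y - cy) - r
    return CircleFit(center=(float(cx), float(cy)), radius=r,
                     rms_residual=float(np.sqrt(np.mean(resid**2))),
                     n_points=len(pts))


# ---------------------------------------------------------------------------
# rotational reference
# ---------------------------------------------------------------------------

def _voxel_azimuths(xs, ys, center, sign):
    az = np.rad2deg(np.arctan2(ys - center[1], xs - center[0]))
    return normalize_deg(sign * az)


def reference_azimuth(stack: ImageStack, circle: CircleFit, mode: str,
                      annotation: CentrioleAnnotation | None = None,
                      channel="marker", z_frame: tuple | None = None,
                      top_q_percent: float = 5.0,
                      distal_fraction: float = 0.3,
                      max_radius_frac: float | None = None):
    """Azimuth (degrees, counterclockwise in distal view) of the reference.

    mode "brightest": intensity centroid of the top-q% voxels of the marker
    channel restricted to the distal ``distal_fraction`` of the z-frame
    (and optionally to ``max_radius_frac`` times the fitted ring radius).
    mode "point"/"basal_foot_point"/"c_end_point": azimuth of the annotated
    point about the fitted ring centre.
    """
    sign = stack.azimuth_sign()
    if mode in ("point", "basal_foot_point", "c_end_point"):
        if annotation is None or annotation.reference_point is None:
            raise ParameterError(f"mode {mode!r} needs an annotated reference point")
        x, y = annotation.reference_point[0], annotation.reference_point[1]
        return float(_voxel_azimuths(np.array([x]), np.array([y]),
                                     circle.center, sign)[0])
    if mode != "brightest":
        raise ParameterError(f"unknown reference mode {mode!r}")

    vol = stack.channel(channel).astype(np.float64)
    nz = vol.shape[0]
    if z_frame is None:
        z0, z1 = 0.0, nz - 1.0
    else:
        z0, z1 = float(z_frame[0]), float(z_frame[1])
    zlo = int(np.clip(np.floor(z1 - distal_fraction * (z1 - z0)), 0, nz - 1))
    zhi = int(np.clip(np.floor(z1) + 1, zlo + 1, nz))
    sub = vol[zlo:zhi]
    if sub.max() <= 0:
        raise NoSignalError("reference channel carries no signal in the distal window")
    zz, yy, xx = np.meshgrid(np.arange(sub.shape[0]), np.arange(sub.shape[1]),
                             np.arange(sub.shape[2]), indexing="ij")
    keep = np.ones_like(sub, dtype=bool)
    if max_radius_frac is not None:
        rr = np.hypot(xx - circle.center[0], yy - circle.center[1])
        keep = rr <= max_radius_frac * circle.radius
    vals = sub[keep]
    if vals.size == 0 or vals.max() <= 0:
        raise NoSignalError("no voxels inside the reference window")
    thr = np.quantile(vals, 1.0 - top_q_percent / 100.0)
    sel = keep & (sub >= thr)
    w = sub[sel]
    az = _voxel_azimuths(xx[sel].astype(float), yy[sel].astype(float),
                         circle.center, sign)
    mean, _ = circular_mean_deg(az, w)
    return float(mean)


def measure_procentriole_azimuth(stack: ImageStack, circle: CircleFit,
                                 z_frame: tuple, channel="wall",
                                 proximal_fraction: float = 0.45,
                                 min_radius_frac: float = 1.25,
                                 top_q_percent: float = 5.0) -> float:
    """Azimuth of the procentriole attachment around the parent.

    Looks at wall-channel signal outside the parent ring (radius above
    ``min_radius_frac`` times the fitted radius) in the proximal part of
    the z-frame and returns the intensity centroid azimuth of its top-q%
    voxels.
    """
    sign = stack.azimuth_sign()
    vol = stack.channel(channel).astype(np.float64)
    nz = vol.shape[0]
    z0, z1 = float(z_frame[0]), float(z_frame[1])
    zlo = int(np.clip(np.floor(z0), 0, nz - 1))
    zhi = int(np.clip(np.ceil(z0 + proximal_fraction * (z1 - z0)), zlo + 1, nz))
    sub = vol[zlo:zhi]
    yy, xx = np.meshgrid(np.arange(sub.shape[1]), np.arange(sub.shape[2]),
                         indexing="ij")
    rr = np.hypot(xx - circle.center[0], yy - circle.center[1])
    keep = np.broadcast_to(rr >= min_radius_frac * circle.radius, sub.shape)
    vals = sub[keep]
    if vals.size == 0 or vals.max() <= 0:
        raise NoSignalError("no signal outside the parent ring")
    thr = np.quantile(vals, 1.0 - top_q_percent / 100.0)
    sel = keep & (sub >= thr)
    zz2, yy2, xx2 = np.nonzero(sel)
    az = _voxel_azimuths(xx2.astype(float), yy2.astype(float), circle.center, sign)
    mean, _ = circular_mean_deg(az, sub[sel])
    return float(mean)


# ---------------------------------------------------------------------------
# full standardization
# ---------------------------------------------------------------------------

def standardize(stack: ImageStack, annotation: CentrioleAnnotation,
                canonical: CanonicalFrame | None = None,
                reference_mode: str | None = None,
                axial_mode: str = "rescale",
                normalize_intensity: bool = False,
                top_q_percent: float = 5.0,
                distal_fraction: float = 0.3,
                reference_channel="marker"):
    """Map one annotated centriole onto the canonical frame.

    Returns ``(StandardCentriole, StandardizationTransform)``.  The
    reference azimuth is sent to canonical azimuth 0 (+x), the fitted ring
    radius to the canonical radius, the fitted centre to the canonical
    axis, and the z-frame onto the canonical axial span ("rescale" mode)
    or translated at native axial scale ("native" mode).
    """
    canonical = canonical or CanonicalFrame()
    mode = reference_mode or annotation.reference_mode
    try:
        vert, Rv = verticalize(stack, annotation.axis_vector())
        circle = fit_reference_circle(annotation.ring_points)
        if mode == "none":
            ref_az = 0.0
        else:
            ref_az = reference_azimuth(
                vert, circle, mode, annotation=annotation,
                channel=reference_channel, z_frame=annotation.z_frame,
                top_q_percent=top_q_percent, distal_fraction=distal_fraction)
    except Exception as exc:
        raise type(exc)(f"particle {annotation.particle_id!r}: {exc}") from exc

    sign = vert.azimuth_sign()
    mirror = sign < 0
    scale = canonical.radius_vox / circle.radius
    rot = -ref_az  # send the reference azimuth to 0
    a = np.deg2rad(rot)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    F = np.diag([1.0, -1.0]) if mirror else np.eye(2)
    M = scale * R @ F
    cc = np.array([canonical.center, canonical.center])
    t = cc - M @ np.asarray(circle.center, dtype=float)

    zp, zd = float(annotation.z_frame[0]), float(annotation.z_frame[1])
    if axial_mode == "rescale":
        az_scale = (canonical.n_planes - 1) / (zd - zp)
        az_off = -zp * az_scale
    elif axial_mode == "native":
        px, pz = vert.require_pitch()
        az_scale = pz / (canonical.axial_pitch_nm * annotation.expansion_factor)
        az_off = (canonical.n_planes - 1) / 2.0 - az_scale * (zp + zd) / 2.0
    else:
        raise ParameterError(f"unknown axial_mode {axial_mode!r}")

    transform = StandardizationTransform(
        in_plane_rotation_deg=rot, scale=scale, translation=t,
        axial_scale=az_scale, axial_offset=az_off, mirror=mirror,
        pre_rotation=Rv)

    # landmark residual: forward-mapped ring points vs the canonical circle
    mapped = transform.apply_points(annotation.ring_points)
    rres = np.hypot(mapped[:, 0] - canonical.center,
                    mapped[:, 1] - canonical.center) - canonical.radius_vox
    transform.landmark_rms_residual = float(np.sqrt(np.mean(rres**2)))

    # inverse-map the canonical grid into the verticalized stack and sample
    n = canonical.lateral_shape
    u = np.arange(n) - canonical.center
    uu, vv = np.meshgrid(u, u, indexing="xy")  # uu varies along x
    Rinv = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    MinvR = (F @ Rinv) / scale
    src_x = circle.center[0] + MinvR[0, 0] * uu + MinvR[0, 1] * vv
    src_y = circle.center[1] + MinvR[1, 0] * uu + MinvR[1, 1] * vv
    zc = np.arange(canonical.n_planes, dtype=float)
    src_z = (zc - az_off) / az_scale

    Zc, Yx = canonical.n_planes, n
    coords = np.empty((3, Zc, Yx, Yx))
    coords[0] = src_z[:, None, None]
    coords[1] = src_y[None, :, :]
    coords[2] = src_x[None, :, :]

    vols = []
    for ci in range(vert.n_channels):
        s = map_coordinates(vert.voxels[ci].astype(np.float64), coords,
                            order=1, mode="constant", cval=np.nan)
        vols.append(s)
    mask = np.isfinite(vols[0])
    volume = np.stack([np.clip(np.nan_to_num(v, nan=0.0), 0.0, None)
                       for v in vols]).astype(np.float32)
    if normalize_intensity:
        roles = vert.channel_roles
        mk = [i for i, r in roles.items() if r == "marker"]
        total = float(volume[mk[0]][mask].sum()) if mk else float(volume.sum())
        if total > 0:
            volume = volume / total

    particle = StandardCentriole(
        volume=volume, mask=mask, particle_id=annotation.particle_id,
        transform=transform, channel_roles=dict(vert.channel_roles),
        canonical=canonical)
    return particle, transform
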