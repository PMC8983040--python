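"""Non-averaging measurements: interpeak asymmetry, lengths, focus intensity.

All nm-valued outputs are calibrated to pre-expansion scale by dividing by
the gel expansion coefficient, so they scale exactly as 1/expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (
    BoundaryPeakError,
    MeasurementError,
    NoPeakError,
    ParameterError,
)
from .stack import ImageStack


@dataclass
class ExpansionCalibration:
    """Gel expansion coefficient measured on the expanded gel."""

    expansion_factor: float

    def __post_init__(self):
        if not self.expansion_factor > 1:
            raise ParameterError("expansion_factor must be > 1")


def _as_factor(calibration) -> float:
    if isinstance(calibration, ExpansionCalibration):
        return calibration.expansion_factor
    f = float(calibration)
    if not f > 0:
        raise ParameterError("expansion factor must be > 0")
    return f


@dataclass
class LineProfile:
    """Intensity samples along a transverse segment."""

    positions_nm: np.ndarray  # expanded-space nm, strictly increasing
    intensities: np.ndarray  # (C, n_samples)
    channel_roles: dict

    def __post_init__(self):
        if len(self.positions_nm) < 5:
            raise ParameterError("a line profile needs at least 5 samples")
        if not np.all(np.diff(self.positions_nm) > 0):
            raise ParameterError("sample positions must be strictly increasing")


@dataclass
class InterpeakResult:
    d_nm: float  # pre-expansion lateral distance between channel peaks
    protein_peak_nm: float  # expanded-space position along the segment
    center_peak_nm: float
    protein_prominence: float
    center_prominence: float


def extract_line_profile(stack: ImageStack, segment, samples_per_voxel: float = 2.0
                         ) -> LineProfile:
    """Bilinear profile along ``segment = (x1, y1, x2, y2, z)`` (voxels)."""
    px, _ = stack.require_pitch()
    x1, y1, x2, y2, z = (float(v) for v in segment)
    length_vox = float(np.hypot(x2 - x1, y2 - y1))
    if length_vox <= 0:
        raise ParameterError("segment has zero length")
    n = max(int(np.ceil(length_vox * samples_per_voxel)) + 1, 5)
    t = np.linspace(0.0, 1.0, n)
    xs = x1 + t * (x2 - x1)
    ys = y1 + t * (y2 - y1)
    zi = int(round(z))
    if not 0 <= zi < stack.voxels.shape[1]:
        raise ParameterError(f"segment plane z={zi} outside stack")
    prof = np.stack([
        map_coordinates(stack.voxels[c, zi].astype(np.float64),
                        np.stack([ys, xs]), order=1, mode="nearest")
        for c in range(stack.n_channels)])
    return LineProfile(positions_nm=t * length_vox * px, intensities=prof,
                       channel_roles=dict(stack.channel_roles))


def _refine_peak(profile: np.ndarray, prominence_mads: float = 3.0):
    """Global maximum refined to subpixel by 3-point parabolic interpolation.

    Returns (position in samples, prominence).  A peak on the boundary has
    no parabolic neighbourhood; one below ``prominence_mads`` times the
    profile MAD (about the median) is rejected.
    """
    i = int(np.argmax(profile))
    if i == 0 or i == len(profile) - 1:
        raise BoundaryPeakError("profile peak lies on the segment boundary")
    med = float(np.median(profile))
    mad = float(np.median(np.abs(profile - med)))
    prominence = float(profile[i] - med)
    if mad > 0 and prominence < prominence_mads * mad:
        raise NoPeakError(
            f"peak prominence {prominence:.3g} below {prominence_mads} x MAD")
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return i + float(np.clip(delta, -0.5, 0.5)), prominence


def interpeak_distance(stack: ImageStack, segment, protein_channel,
                       center_channel, calibration,
                       prominence_mads: float = 3.0) -> InterpeakResult:
    """Lateral interpeak distance d between a protein and the centriole centre.

    Both channels are profiled along the segment; each global maximum is
    refined to subpixel, and ``d = |pos_protein - pos_center| / expansion``
    in pre-expansion nm.
    """
    factor = _as_factor(calibration)
    lp = extract_line_profile(stack, segment)
    pitch = lp.positions_nm[1] - lp.positions_nm[0]
    ip = stack.channel_index(protein_channel)
    ic = stack.channel_index(center_channel)
    pp, prom_p = _refine_peak(lp.intensities[ip], prominence_mads)
    pc, prom_c = _refine_peak(lp.intensities[ic], prominence_mads)
    pos_p = pp * pitch
    pos_c = pc * pitch
    return InterpeakResult(
        d_nm=abs(pos_p - pos_c) / factor,
        protein_peak_nm=pos_p, center_peak_nm=pos_c,
        protein_prominence=prom_p, center_prominence=prom_c)


# ---------------------------------------------------------------------------
# length
# ---------------------------------------------------------------------------

def _axial_profile(stack: ImageStack, channel, center=None, radii_vox=None):
    vol = stack.channel(channel).astype(np.float64)
    if center is None or radii_vox is None:
        return vol.sum(axis=(1, 2))
    yy, xx = np.meshgrid(np.arange(vol.shape[1]), np.arange(vol.shape[2]),
                         indexing="ij")
    rr = np.hypot(xx - center[0], yy - center[1])
    sel = (rr >= radii_vox[0]) & (rr <= radii_vox[1])
    return vol[:, sel].sum(axis=1)


def _half_max_crossings(profile: np.ndarray, fraction: float = 0.5):
    """(first, last) subplane crossings of fraction*max, by linear interpolation."""
    pmax = float(profile.max())
    if pmax <= 0:
        raise MeasurementError("axial profile is empty")
    half = fraction * pmax
    above = profile >= half
    if not np.any(above) or np.all(above):
        raise MeasurementError("no half-maximum crossing (flat or saturated profile)")
    idx = np.nonzero(above)[0]
    first, last = int(idx[0]), int(idx[-1])

    def interp_up(i):
        if i == 0:
            return 0.0
        y0, y1 = profile[i - 1], profile[i]
        return i - 1 + (half - y0) / (y1 - y0)

    def interp_down(i):
        if i == len(profile) - 1:
            return float(i)
        y0, y1 = profile[i], profile[i + 1]
        return i + (y0 - half) / (y0 - y1)

    return interp_up(first), interp_down(last)


def measure_length(stack: ImageStack, calibration, mode: str = "daughter",
                   wall_channel="wall", appendage_channel="appendage",
                   z_frame: tuple | None = None, center=None,
                   annulus_vox: tuple | None = None,
                   threshold_fraction: float = 0.5) -> float:
    """Centriole length in pre-expansion nm from the verticalized stack.

    The wall channel's axial profile (integrated over the ring annulus, or
    the whole plane) gives the proximal end as its proximal
    ``threshold_fraction``-of-maximum crossing.  The distal end is the
    distal crossing ("daughter" mode, wall extent) or the axial peak of
    the appendage channel ("mother" mode, wall proximal end to
    distal-appendage position).
    """
    factor = _as_factor(calibration)
    px, pz = stack.require_pitch()
    if mode not in ("daughter", "mother"):
        raise ParameterError(f"unknown length mode {mode!r}")
    prof = _axial_profile(stack, wall_channel, center, annulus_vox)
    if z_frame is not None:
        z0 = int(np.clip(np.floor(z_frame[0]), 0, len(prof) - 1))
        z1 = int(np.clip(np.ceil(z_frame[1]), 0, len(prof) - 1))
        if z1 - z0 < 2:
            raise MeasurementError("z-frame spans fewer than 2 planes")
        windowed = np.zeros_like(prof)
        windowed[z0:z1 + 1] = prof[z0:z1 + 1]
        prof = windowed
    z_prox, z_dist = _half_max_crossings(prof, threshold_fraction)
    if mode == "mother":
        try:
            aprof = _axial_profile(stack, appendage_channel, center, None)
        except Exception as exc:
            raise MeasurementError(
                f"mother mode needs an appendage channel: {exc}") from exc
        z_dist, _ = _refine_peak(aprof, prominence_mads=0.0)
    length_nm = (z_dist - z_prox) * pz / factor
    if length_nm <= 0:
        raise MeasurementError("non-positive length; check channel assignment")
    return float(length_nm)


# ---------------------------------------------------------------------------
# focus intensity
# ---------------------------------------------------------------------------

@dataclass
class FocusIntensity:
    value: float  # background-subtracted integrated intensity
    background_per_voxel: float
    disk_voxels: int
    clipped: bool  # annulus touched the stack boundary


def quantify_focus_intensity(stack: ImageStack, center, inner_radius: float,
                             outer_radius: float, channel="marker"
                             ) -> FocusIntensity:
    """Integrated focus intensity minus the local cytoplasmic background.

    Sums the channel over the inner disk across the whole z-series and
    subtracts the median annulus intensity (a robust background estimate)
    times the disk voxel count.
    """
    if not outer_radius > inner_radius > 0:
        raise ParameterError("need outer_radius > inner_radius > 0")
    vol = stack.channel(channel).astype(np.float64)
    nz, ny, nx = vol.shape
    cx, cy = float(center[0]), float(center[1])
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    rr = np.hypot(xx - cx, yy - cy)
    disk = rr <= inner_radius
    ann = (rr > inner_radius) & (rr <= outer_radius)
    clipped = bool(cx - outer_radius < 0 or cy - outer_radius < 0
                   or cx + outer_radius > nx - 1 or cy + outer_radius > ny - 1)
    if not np.any(disk):
        raise ParameterError("inner disk selects no voxels")
    disk_vals = vol[:, disk]
    bg = float(np.median(vol[:, ann])) if np.any(ann) else 0.0
    n_disk = int(disk_vals.size)
    return FocusIntensity(
        value=float(disk_vals.sum() - bg * n_disk),
        background_per_voxel=bg, disk_voxels=n_disk, clipped=clipped)
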