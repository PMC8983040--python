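"""Mask-aware particle averaging and azimuthal readout of the average.

Standardized particles are combined by a voxelwise Welford accumulation
restricted to each particle's validity mask, producing a mean volume, a
per-voxel SD and a contribution count.  The rotational structure of the
average is summarized as an azimuthal intensity profile within a radial
annulus and axial window, with per-triplet mass assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .angles import circular_mean_deg, normalize_deg, signed_circ_diff_deg
from .errors import ParameterError
from .standardize import CanonicalFrame, StandardCentriole


@dataclass
class AverageModel:
    """Voxelwise average over standardized particles."""

    mean: np.ndarray  # (C, Z, Y, X); NaN where count == 0
    sd: np.ndarray  # same shape; 0 where count <= 1
    count: np.ndarray  # (Z, Y, X) integer contributions
    n_particles: int
    particle_ids: list
    channel_roles: dict
    canonical: CanonicalFrame
    reference_mode: str | None = None


@dataclass
class AzimuthalProfile:
    """Mean intensity per angular bin within an annulus and axial window."""

    bin_centers_deg: np.ndarray
    bin_means: np.ndarray
    peak_azimuth_deg: float
    peak_triplet: int
    triplet_azimuths_deg: np.ndarray
    triplet_means: np.ndarray
    resultant: float
    stable: bool
    baseline: float = 0.0


def average_standardized(particles: list, weights=None,
                         reference_mode: str | None = None) -> AverageModel:
    """Welford mean/SD over particles, honouring validity masks.

    All particles must share the canonical grid; a mismatch raises an
    error naming the offending particle.  ``weights`` (optional, one per
    particle) switch to a weighted mean and weighted SD (West's
    incremental scheme); the default is unweighted.
    """
    if len(particles) == 0:
        raise ParameterError("need at least one particle to average")
    ref = particles[0]
    shape = ref.volume.shape
    count = np.zeros(shape[1:], dtype=np.int32)
    wsum = np.zeros(shape[1:], dtype=np.float64)
    mean = np.zeros(shape, dtype=np.float64)
    m2 = np.zeros(shape, dtype=np.float64)
    if weights is None:
        weights = np.ones(len(particles))
    weights = np.asarray(weights, dtype=float)
    for p, w in zip(particles, weights):
        if p.volume.shape != shape:
            raise ParameterError(
                f"particle {p.particle_id!r} grid {p.volume.shape} does not "
                f"match {shape}")
        if p.channel_roles != ref.channel_roles:
            raise ParameterError(
                f"particle {p.particle_id!r} channel roles differ")
        m = p.mask
        count[m] += 1
        wnew = wsum + w * m
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(m, p.volume - mean, 0.0)
            rate = np.where(wnew > 0, (w * m) / np.maximum(wnew, 1e-300), 0.0)
            mean = mean + delta * rate
            m2 = m2 + np.where(m, w * delta * (p.volume - mean), 0.0)
        wsum = wnew
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(np.clip(m2 / np.maximum(wsum, 1e-300), 0.0, None))
    sd[:, count <= 1] = 0.0
    mean[:, count == 0] = np.nan
    return AverageModel(
        mean=mean, sd=sd, count=count, n_particles=len(particles),
        particle_ids=[p.particle_id for p in particles],
        channel_roles=dict(ref.channel_roles), canonical=ref.canonical,
        reference_mode=reference_mode)


def single_particle_model(particle: StandardCentriole) -> AverageModel:
    """Wrap one standardized particle as a one-particle AverageModel."""
    return average_standardized([particle])


def azimuthal_profile(model: AverageModel, channel="marker",
                      annulus: tuple = (0.6, 1.0),
                      axial_window: tuple = (0.7, 1.0),
                      bin_deg: float = 1.0,
                      n_triplets: int = 9,
                      triplet1_azimuth_deg: float | None = None,
                      triplet_window_deg: float = 5.0,
                      stability_threshold: float = 0.1) -> AzimuthalProfile:
    """Azimuthal intensity profile of the average.

    The annulus is given as fractions of the canonical radius (default
    0.6-1.0, the luminal side where the asymmetric signal lives); the
    axial window as fractions of the canonical axial span (default the
    distal 30%).  Bins that catch no grid voxel are filled by circular
    interpolation.  The peak azimuth is the baseline-subtracted circular
    centroid of the contiguous bin cluster around the maximum that stays
    above half the peak.  Triplet indices are assigned counterclockwise
    from ``triplet1_azimuth_deg`` (default: the triplet-grid point closest
    to the peak becomes triplet 1); each triplet's mean is taken over bins
    within ``triplet_window_deg`` of its azimuth — narrow on purpose, so
    neighbouring lobes 40 degrees away do not bleed into the readout.
    """
    if not 0 <= annulus[0] < annulus[1]:
        raise ParameterError("annulus fractions must satisfy 0 <= lo < hi")
    if not 0 <= axial_window[0] < axial_window[1] <= 1:
        raise ParameterError("axial window fractions must lie in [0, 1]")
    can = model.canonical
    ci = [i for i, r in model.channel_roles.items() if r == channel]
    ch = ci[0] if ci else int(channel) if not isinstance(channel, str) else None
    if ch is None:
        raise ParameterError(f"no channel with role {channel!r}")
    vol = model.mean[ch]
    nz = vol.shape[0]
    zlo = int(np.floor(axial_window[0] * (nz - 1)))
    zhi = int(np.ceil(axial_window[1] * (nz - 1))) + 1
    sub = vol[zlo:zhi]

    n = can.lateral_shape
    u = np.arange(n) - can.center
    xx, yy = np.meshgrid(u, u, indexing="xy")
    rr = np.hypot(xx, yy) / can.radius_vox
    ann = (rr >= annulus[0]) & (rr <= annulus[1])
    if not np.any(ann):
        raise ParameterError("annulus selects no voxels")
    az = normalize_deg(np.rad2deg(np.arctan2(yy, xx)))

    nbins = int(round(360.0 / bin_deg))
    bin_idx = np.minimum((az / bin_deg).astype(int), nbins - 1)
    bins = np.full(nbins, np.nan)
    lat_sel = ann
    flat_idx = bin_idx[lat_sel]
    vals = sub[:, lat_sel]  # (nzwin, npix)
    finite = np.isfinite(vals)
    sums = np.zeros(nbins)
    cnts = np.zeros(nbins)
    for zi in range(vals.shape[0]):
        good = finite[zi]
        sums += np.bincount(flat_idx[good], weights=vals[zi][good], minlength=nbins)
        cnts += np.bincount(flat_idx[good], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        bins = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_deg

    finite_bins = np.isfinite(bins)
    if not np.any(finite_bins):
        raise ParameterError("profile is empty (no defined voxels in window)")
    if not np.all(finite_bins):
        bins = np.interp(centers, centers[finite_bins], bins[finite_bins],
                         period=360.0)
        finite_bins = np.isfinite(bins)
    baseline = float(np.nanmin(bins))
    excess = bins - baseline
    peak_i = int(np.argmax(excess))
    half = excess[peak_i] / 2.0
    above = excess >= half
    # contiguous cluster (circular) containing the peak
    cluster = np.zeros(nbins, dtype=bool)
    i = peak_i
    while above[i % nbins] and not cluster[i % nbins]:
        cluster[i % nbins] = True
        i += 1
    i = peak_i - 1
    while above[i % nbins] and not cluster[i % nbins]:
        cluster[i % nbins] = True
        i -= 1
    peak_az, _ = circular_mean_deg(centers[cluster], excess[cluster])
    mean_az, resultant = circular_mean_deg(centers, np.clip(excess, 0, None))
    stable = bool(resultant >= stability_threshold)

    spacing = 360.0 / n_triplets
    if triplet1_azimuth_deg is None:
        offset = normalize_deg(peak_az) % spacing
        grid = normalize_deg(offset + spacing * np.arange(n_triplets))
        k0 = int(np.argmin(np.abs(signed_circ_diff_deg(grid, peak_az))))
        t1 = grid[k0]
    else:
        t1 = normalize_deg(triplet1_azimuth_deg)
    triplet_az = normalize_deg(t1 + spacing * np.arange(n_triplets))
    tm = np.empty(n_triplets)
    half = min(triplet_window_deg, spacing / 2.0)
    for k, ta in enumerate(triplet_az):
        d = np.abs(signed_circ_diff_deg(centers, ta))
        selbins = finite_bins & (d <= half)
        tm[k] = float(np.nanmean(bins[selbins])) if np.any(selbins) else np.nan
    d_to_peak = np.abs(signed_circ_diff_deg(triplet_az, peak_az))
    peak_triplet = int(np.argmin(d_to_peak)) + 1

    return AzimuthalProfile(
        bin_centers_deg=centers, bin_means=bins,
        peak_azimuth_deg=float(normalize_deg(peak_az)),
        peak_triplet=peak_triplet, triplet_azimuths_deg=triplet_az,
        triplet_means=tm, resultant=float(resultant), stable=stable,
        baseline=baseline)


def triplet_excess_ratio(profile: AzimuthalProfile, numerator_triplet: int,
                         denominator_triplet: int) -> float:
    """Intensity ratio of two triplets above the wall-associated level.

    The faint full-length staining along all triplets adds a common
    per-triplet pedestal on top of the distal asymmetric lobes; the median
    bin mean of the remaining triplets estimates that pedestal, and the
    ratio of pedestal-subtracted means isolates the lobe asymmetry.
    """
    tm = np.asarray(profile.triplet_means, dtype=float)
    others = [v for k, v in enumerate(tm, start=1)
              if k not in (numerator_triplet, denominator_triplet)
              and np.isfinite(v)]
    pedestal = float(np.median(others)) if others else 0.0
    num = tm[numerator_triplet - 1] - pedestal
    den = tm[denominator_triplet - 1] - pedestal
    if den <= 0:
        raise ParameterError("denominator triplet has no excess over pedestal")
    return float(num / den)


def longitudinal_projection(model: AverageModel, channel="marker",
                            slab_nm: float = 40.0) -> np.ndarray:
    """Max projection through an axis-containing slab (presentation only)."""
    can = model.canonical
    half = max(int(round(slab_nm / can.lateral_pitch_nm / 2)), 1)
    ci = [i for i, r in model.channel_roles.items() if r == channel][0]
    mid = int(round(can.center))
    slab = model.mean[ci][:, mid - half:mid + half + 1, :]
    with np.errstate(invalid="ignore"):
        return np.nanmax(slab, axis=1)
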