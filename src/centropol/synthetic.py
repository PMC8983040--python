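"""Synthetic U-ExM centriole stacks with exhaustive ground truth.

The generator renders the geometry the downstream pipeline is built to
measure: a ninefold ring of microtubule-triplet rods, a rotationally
asymmetric distal luminal marker enriched on one or two consecutive
triplets (the brighter one ~50% above its counterclockwise neighbour),
an optional basal-foot lobe, an optional orthogonal procentriole, and an
optional distal-appendage ring.  Geometry is specified pre-expansion in
nanometres, scaled by the gel expansion factor, posed in 3D, convolved
with a Gaussian PSF and degraded by Poisson + Gaussian read noise.

Every stochastic choice derives from a single named seed through
``numpy.random.SeedSequence([seed, particle_index])`` so any particle of a
cohort is regenerable in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .angles import circular_mean_deg, normalize_deg, rot_y, rot_z, rotation_to_z
from .errors import GeometryError, ParameterError
from .stack import ImageStack

# emitter line densities (arbitrary intensity per expanded nm of rod)
_WALL_DENSITY = 1.0
_MARKER_DENSITY = 3.0
_BASAL_FOOT_AMP = 800.0
_APPENDAGE_POINT_AMP = 300.0
_PROCENTRIOLE_GAP_NM = 30.0  # pre-expansion radial gap parent wall -> procentriole base
_CONTACT_TOL_NM = 25.0  # pre-expansion wall-to-wall contact tolerance


@dataclass
class Pose:
    """Rigid pose of a centriole inside its stack.

    The long axis starts along +z; the pose first applies the in-plane
    rotation about z, then tilts the axis by ``tilt_deg`` toward the
    direction ``tilt_direction_deg`` in the xy-plane, then translates.
    """

    tilt_deg: float = 0.0
    tilt_direction_deg: float = 0.0
    rotation_deg: float = 0.0
    translation_nm: tuple = (0.0, 0.0, 0.0)

    def tilt_matrix(self) -> np.ndarray:
        return (
            rot_z(self.tilt_direction_deg)
            @ rot_y(self.tilt_deg)
            @ rot_z(-self.tilt_direction_deg)
        )

    def matrix(self) -> np.ndarray:
        return self.tilt_matrix() @ rot_z(self.rotation_deg)

    def axis_vector(self) -> np.ndarray:
        v = self.tilt_matrix() @ np.array([0.0, 0.0, 1.0])
        return v / np.linalg.norm(v)


@dataclass
class NoiseModel:
    """Poisson photon noise plus additive Gaussian read noise.

    ``peak_snr`` sets the photon scale so the brightest voxel of the
    reference channel carries ``peak_snr**2`` expected photons (hence a
    shot-noise SNR of ``peak_snr`` there).  ``None`` disables all noise.
    ``read_noise_frac`` is the read-noise sigma as a fraction of that
    reference peak.
    """

    peak_snr: float | None = 10.0
    read_noise_frac: float = 0.02
    reference_role: str = "marker"

    @property
    def enabled(self) -> bool:
        return self.peak_snr is not None and self.peak_snr > 0

    def apply(self, volumes: dict, rng: np.random.Generator) -> dict:
        if not self.enabled:
            return volumes
        ref = volumes.get(self.reference_role)
        if ref is None:
            ref = next(iter(volumes.values()))
        peak = float(max(v.max() for v in volumes.values())) if ref.max() == 0 else float(ref.max())
        if peak <= 0:
            return volumes
        scale = self.peak_snr**2 / peak
        out = {}
        for role, v in volumes.items():
            noisy = rng.poisson(v * scale).astype(np.float64) / scale
            noisy += rng.normal(0.0, self.read_noise_frac * peak, size=v.shape)
            out[role] = np.clip(noisy, 0.0, None)
        return out


@dataclass
class GeneratorParams:
    """Full parameterization of one synthetic centriole.

    Lengths and radii are pre-expansion nanometres; the rendered stack
    lives in expanded space (everything multiplied by ``expansion_factor``).
    Azimuths are degrees, counterclockwise-positive in the distal view.
    """

    ring_radius_nm: float = 115.0
    centriole_length_nm: float = 427.0
    n_triplets: int = 9
    marker_azimuth_deg: float = 0.0
    marker_intensity_ratio: float = 1.5
    marker_axial_fraction: float = 0.25
    marker_radius_fraction: float = 0.8
    marker_lobe_offsets_deg: tuple | None = None
    marker_lobe_relative_amps: tuple | None = None
    faint_wall_fraction: float = 0.1
    intensity_scale: float = 1.0
    basal_foot_azimuth_offset_deg: float | None = None
    include_appendage: bool = False
    procentriole_length_nm: float = 100.0
    expansion_factor: float = 4.0
    voxel_pitch_nm: float = 30.0
    voxel_pitch_z_nm: float = 100.0
    psf_sigma_nm: float = 80.0
    psf_sigma_z_nm: float = 200.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    pose: Pose = field(default_factory=Pose)
    seed: int = 0
    shape: tuple | None = None  # (Z, Y, X); None = auto-size

    def validate(self) -> None:
        if self.n_triplets < 3:
            raise ParameterError("n_triplets must be >= 3")
        if self.marker_intensity_ratio < 1.0:
            raise ParameterError("marker_intensity_ratio must be >= 1")
        if not 0.0 < self.marker_axial_fraction <= 1.0:
            raise ParameterError("marker_axial_fraction must lie in (0, 1]")
        if self.expansion_factor <= 1.0:
            raise ParameterError("expansion_factor must be > 1")
        for name in ("ring_radius_nm", "centriole_length_nm", "voxel_pitch_nm",
                     "voxel_pitch_z_nm", "psf_sigma_nm", "psf_sigma_z_nm",
                     "procentriole_length_nm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    def lobe_geometry(self) -> tuple:
        """(azimuths_deg, relative_amps) of the asymmetric marker lobes."""
        spacing = 360.0 / self.n_triplets
        if self.marker_lobe_offsets_deg is None:
            offsets = (0.0, spacing)
        else:
            offsets = tuple(self.marker_lobe_offsets_deg)
        if self.marker_lobe_relative_amps is None:
            amps = (1.0, 1.0 / self.marker_intensity_ratio)[: len(offsets)]
        else:
            amps = tuple(self.marker_lobe_relative_amps)
        if len(amps) != len(offsets):
            raise ParameterError("marker lobe offsets and amplitudes differ in length")
        az = tuple(normalize_deg(self.marker_azimuth_deg + o) for o in offsets)
        return az, amps


@dataclass
class GroundTruth:
    """Everything the generator knows about one particle.

    Landmark coordinates are exported in the frames the annotation schema
    uses: ``axis_points_vox`` in the raw (posed) stack, ring / reference /
    z-frame landmarks in the verticalized stack.
    """

    params: GeneratorParams
    axis_vector: np.ndarray
    triplet_azimuths_deg: np.ndarray
    marker_centroid_azimuth_deg: float
    marker_lobe_azimuths_deg: np.ndarray
    marker_lobe_amps: np.ndarray
    z_range: tuple  # (proximal, distal) plane coordinates, verticalized frame
    ring_points_vert: np.ndarray  # (n, 2) voxel (x, y)
    reference_point_vert: np.ndarray  # (3,) voxel (x, y, z) of brightest lobe
    axis_points_vox: np.ndarray  # (2, 3) voxel (x, y, z), raw stack
    peak_locations: dict  # role -> (x, y, z) voxel of noiseless argmax
    procentriole_azimuth_deg: float | None = None
    procentriole_marker_azimuth_deg: float | None = None
    procentriole_axis_vector: np.ndarray | None = None
    overlap_warning: bool = False

    def __post_init__(self):
        n = np.linalg.norm(self.axis_vector)
        assert abs(n - 1.0) < 1e-9, "axis_vector must be unit norm"

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return _jsonable(d)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        p = dict(d.pop("params"))
        p["noise"] = NoiseModel(**p["noise"])
        p["pose"] = Pose(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in p["pose"].items()})
        for key in ("marker_lobe_offsets_deg", "marker_lobe_relative_amps", "shape"):
            if p.get(key) is not None:
                p[key] = tuple(p[key])
        params = GeneratorParams(**p)
        for key in ("axis_vector", "triplet_azimuths_deg", "marker_lobe_azimuths_deg",
                    "marker_lobe_amps", "ring_points_vert", "reference_point_vert",
                    "axis_points_vox"):
            d[key] = np.asarray(d[key], dtype=float)
        if d.get("procentriole_axis_vector") is not None:
            d["procentriole_axis_vector"] = np.asarray(
                d["procentriole_axis_vector"], dtype=float)
        d["z_range"] = tuple(d["z_range"])
        d["peak_locations"] = {k: tuple(v) for k, v in d["peak_locations"].items()}
        return cls(params=params, **d)

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_annotation(self, particle_id: str, reference_mode: str = "point"):
        """Export the landmark set the standardization stage consumes."""
        from .io import CentrioleAnnotation

        return CentrioleAnnotation(
            particle_id=particle_id,
            ring_points=self.ring_points_vert.copy(),
            reference_point=tuple(self.reference_point_vert),
            reference_mode=reference_mode,
            axis_points=self.axis_points_vox.copy(),
            z_frame=(float(self.z_range[0]), float(self.z_range[1])),
            expansion_factor=self.params.expansion_factor,
            view_convention="distal",
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _rod_points(base: np.ndarray, direction: np.ndarray, length: float,
                density: float, step: float):
    """Point emitters along a rod; total intensity = density * length."""
    n = max(int(np.ceil(length / step)), 2)
    t = np.linspace(0.0, length, n)
    pts = base[None, :] + t[:, None] * direction[None, :]
    amps = np.full(n, density * length / n)
    return pts, amps


def _splat(points_vox: np.ndarray, amps: np.ndarray, shape: tuple) -> np.ndarray:
    """Trilinear deposition of point emitters onto a (Z, Y, X) grid."""
    vol = np.zeros(shape, dtype=np.float64)
    if len(points_vox) == 0:
        return vol
    # points are (x, y, z); grid is (z, y, x)
    zyx = points_vox[:, ::-1]
    base = np.floor(zyx).astype(int)
    frac = zyx - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                idx = base + (dz, dy, dx)
                w = (
                    (frac[:, 0] if dz else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dx else 1 - frac[:, 2])
                )
                ok = np.all((idx >= 0) & (idx < shape), axis=1)
                np.add.at(vol, (idx[ok, 0], idx[ok, 1], idx[ok, 2]), w[ok] * amps[ok])
    return vol


def _build_emitters(p: GeneratorParams) -> dict:
    """Emitter clouds per channel role, in the canonical (unposed) frame.

    Coordinates are expanded-space nm, centriole axis along +z, ring centred
    on the origin, z spanning [-L/2, +L/2] with the distal end at +L/2.
    """
    e = p.expansion_factor
    R = p.ring_radius_nm * e
    L = p.centriole_length_nm * e
    step = min(p.voxel_pitch_nm, p.voxel_pitch_z_nm) / 2.0
    ez = np.array([0.0, 0.0, 1.0])

    out: dict = {}
    lobe_az, lobe_amps = p.lobe_geometry()
    spacing = 360.0 / p.n_triplets
    triplet_az = normalize_deg(p.marker_azimuth_deg + spacing * np.arange(p.n_triplets))

    wall_pts, wall_amps = [], []
    for az in triplet_az:
        a = np.deg2rad(az)
        base = np.array([R * np.cos(a), R * np.sin(a), -L / 2])
        pts, amps = _rod_points(base, ez, L, _WALL_DENSITY * p.intensity_scale, step)
        wall_pts.append(pts)
        wall_amps.append(amps)
    out["wall"] = (np.vstack(wall_pts), np.concatenate(wall_amps))

    # asymmetric distal luminal lobes + faint full-length wall-associated component
    mk_pts, mk_amps = [], []
    Rm = R * p.marker_radius_fraction
    Lm = L * p.marker_axial_fraction
    for az, rel in zip(lobe_az, lobe_amps):
        a = np.deg2rad(az)
        base = np.array([Rm * np.cos(a), Rm * np.sin(a), L / 2 - Lm])
        pts, amps = _rod_points(
            base, ez, Lm, _MARKER_DENSITY * rel * p.intensity_scale, step)
        mk_pts.append(pts)
        mk_amps.append(amps)
    if p.faint_wall_fraction > 0:
        faint = _MARKER_DENSITY * max(lobe_amps) * p.faint_wall_fraction
        for az in triplet_az:
            a = np.deg2rad(az)
            base = np.array([R * np.cos(a), R * np.sin(a), -L / 2])
            pts, amps = _rod_points(base, ez, L, faint * p.intensity_scale, step)
            mk_pts.append(pts)
            mk_amps.append(amps)
    out["marker"] = (np.vstack(mk_pts), np.concatenate(mk_amps))

    if p.basal_foot_azimuth_offset_deg is not None:
        # basal foot sits opposite the marker, shifted clockwise by the offset
        az = np.deg2rad(p.marker_azimuth_deg + 180.0 - p.basal_foot_azimuth_offset_deg)
        pos = np.array([1.6 * R * np.cos(az), 1.6 * R * np.sin(az), -L / 4])
        out["reference"] = (pos[None, :],
                            np.array([_BASAL_FOOT_AMP * p.intensity_scale]))

    if p.include_appendage:
        a = np.deg2rad(triplet_az)
        pts = np.stack([1.4 * R * np.cos(a), 1.4 * R * np.sin(a),
                        np.full(p.n_triplets, L / 2)], axis=1)
        out["appendage"] = (pts, np.full(p.n_triplets,
                                         _APPENDAGE_POINT_AMP * p.intensity_scale))
    return out


def _render(p: GeneratorParams, emitters: dict):
    """Pose, auto-frame, splat and blur all channels. Returns volumes + frame."""
    Rpose = p.pose.matrix()
    t = np.asarray(p.pose.translation_nm, dtype=float)
    posed = {role: (pts @ Rpose.T + t, amps) for role, (pts, amps) in emitters.items()}

    allpts = np.vstack([pts for pts, _ in posed.values()])
    margin = np.array([3 * p.psf_sigma_nm + 2 * p.voxel_pitch_nm,
                       3 * p.psf_sigma_nm + 2 * p.voxel_pitch_nm,
                       3 * p.psf_sigma_z_nm + 2 * p.voxel_pitch_z_nm])
    lo = allpts.min(axis=0) - margin
    hi = allpts.max(axis=0) + margin
    pitches = np.array([p.voxel_pitch_nm, p.voxel_pitch_nm, p.voxel_pitch_z_nm])
    if p.shape is None:
        nvox = np.ceil((hi - lo) / pitches).astype(int) + 1  # (x, y, z) counts
        shape = (int(nvox[2]), int(nvox[1]), int(nvox[0]))
        origin = lo
    else:
        # fixed shape: centre the volume on the posed ring centre so that
        # rotating about the volume centre undoes the pose exactly
        shape = tuple(int(s) for s in p.shape)
        extent = np.array([shape[2], shape[1], shape[0]]) * pitches
        # ring centre on the exact rotation centre voxel (n - 1) / 2
        origin = t - (np.array([shape[2], shape[1], shape[0]]) - 1) / 2.0 * pitches
        for axis_idx, name in ((2, "z"), (1, "y"), (0, "x")):
            if lo[axis_idx] < origin[axis_idx] or \
                    hi[axis_idx] > origin[axis_idx] + extent[axis_idx]:
                need = max(hi[axis_idx] - t[axis_idx],
                           t[axis_idx] - lo[axis_idx]) * 2
                raise GeometryError(
                    f"stack extent too small along {name}: needs "
                    f"{need:.0f} nm, has {extent[axis_idx]:.0f} nm")
    sigma_vox = (p.psf_sigma_z_nm / p.voxel_pitch_z_nm,
                 p.psf_sigma_nm / p.voxel_pitch_nm,
                 p.psf_sigma_nm / p.voxel_pitch_nm)
    volumes = {}
    for role, (pts, amps) in posed.items():
        vox = (pts - origin) / pitches
        volumes[role] = gaussian_filter(_splat(vox, amps, shape), sigma_vox)
    return volumes, origin, pitches, shape


def _vert_vox(pts_nm_canonical, Rpose, t, origin, pitches, shape, rotation_deg):
    """Map canonical-frame nm points to voxel coords of the verticalized stack.

    Verticalization rotates the posed volume about its centre (in physical
    space) by the inverse tilt, so a canonical point p lands at
    Rz(rotation) @ p + Rtilt^T @ (t + origin-offset) relative to the centre.
    """
    c_vox = (np.array([shape[2], shape[1], shape[0]], dtype=float) - 1) / 2.0
    c_nm = origin + c_vox * pitches
    Rv = Rpose @ rot_z(-rotation_deg)  # tilt-only part of the pose
    pts = np.atleast_2d(np.asarray(pts_nm_canonical, dtype=float))
    posed = pts @ Rpose.T + t
    vert = (posed - c_nm) @ Rv + c_nm  # right-multiplying by Rv applies Rv^T
    return c_vox + (vert - c_nm) / pitches


def generate_centriole(params: GeneratorParams):
    """Render one synthetic centriole.

    Returns
    -------
    (ImageStack, GroundTruth)
    """
    params.validate()
    emitters = _build_emitters(params)
    volumes, origin, pitches, shape = _render(params, emitters)

    peak_locations = {}
    for role, v in volumes.items():
        z, y, x = np.unravel_index(int(np.argmax(v)), v.shape)
        peak_locations[role] = (float(x), float(y), float(z))

    rng = np.random.default_rng(params.seed)
    noisy = params.noise.apply(volumes, rng)

    roles = [r for r in ("wall", "marker", "reference", "appendage") if r in noisy]
    voxels = np.stack([noisy[r] for r in roles]).astype(np.float32)
    stack = ImageStack(
        voxels=voxels,
        voxel_pitch_nm=params.voxel_pitch_nm,
        voxel_pitch_z_nm=params.voxel_pitch_z_nm,
        channel_roles={i: r for i, r in enumerate(roles)},
        view_convention="distal",
    )

    truth = _ground_truth(params, origin, pitches, shape, peak_locations)
    return stack, truth


def _ground_truth(params, origin, pitches, shape, peak_locations,
                  pro_azimuth=None, pro_marker_azimuth=None, pro_axis=None,
                  overlap=False):
    p = params
    e = p.expansion_factor
    R = p.ring_radius_nm * e
    L = p.centriole_length_nm * e
    Rpose = p.pose.matrix()
    t = np.asarray(p.pose.translation_nm, dtype=float)
    rho = p.pose.rotation_deg
    spacing = 360.0 / p.n_triplets
    triplet_az = normalize_deg(p.marker_azimuth_deg + spacing * np.arange(p.n_triplets))
    lobe_az, lobe_amps = p.lobe_geometry()
    centroid, _ = circular_mean_deg(lobe_az, lobe_amps)

    def vert(pts):
        return _vert_vox(pts, Rpose, t, origin, pitches, shape, rho)

    a = np.deg2rad(triplet_az)
    ring = np.stack([R * np.cos(a), R * np.sin(a), np.zeros_like(a)], axis=1)
    ring_vert = vert(ring)[:, :2]

    a1 = np.deg2rad(lobe_az[int(np.argmax(lobe_amps))])
    Rm = R * p.marker_radius_fraction
    ref = np.array([Rm * np.cos(a1), Rm * np.sin(a1),
                    L / 2 - 0.5 * L * p.marker_axial_fraction])
    ref_vert = vert(ref)[0]

    zpts = vert(np.array([[0.0, 0.0, -L / 2], [0.0, 0.0, L / 2]]))
    z_range = (float(zpts[0, 2]), float(zpts[1, 2]))

    axis_nm = np.stack([Rpose @ np.array([0.0, 0.0, -L / 4]) + t,
                        Rpose @ np.array([0.0, 0.0, L / 4]) + t])
    axis_vox = axis_nm / pitches - origin / pitches

    return GroundTruth(
        params=p,
        axis_vector=p.pose.axis_vector(),
        triplet_azimuths_deg=triplet_az,
        marker_centroid_azimuth_deg=float(centroid),
        marker_lobe_azimuths_deg=np.asarray(lobe_az, dtype=float),
        marker_lobe_amps=np.asarray(lobe_amps, dtype=float),
        z_range=z_range,
        ring_points_vert=ring_vert,
        reference_point_vert=ref_vert,
        axis_points_vox=axis_vox,
        peak_locations=peak_locations,
        procentriole_azimuth_deg=pro_azimuth,
        procentriole_marker_azimuth_deg=pro_marker_azimuth,
        procentriole_axis_vector=pro_axis,
        overlap_warning=overlap,
    )


def generate_diplosome(params: GeneratorParams, procentriole_azimuth_deg: float,
                       procentriole_marker_azimuth_deg: float = 0.0):
    """Render a parent centriole with an orthogonal procentriole.

    The procentriole grows radially outward from the parent's proximal
    region at the stated azimuth; its own asymmetric marker sits at its
    distal (outward) end, at an azimuth measured around the procentriole
    axis starting from the parent long-axis direction.
    """
    params.validate()
    pa = normalize_deg(procentriole_azimuth_deg)
    pma = normalize_deg(procentriole_marker_azimuth_deg)
    e = params.expansion_factor
    Rpar = params.ring_radius_nm * e
    Lpar = params.centriole_length_nm * e
    Rpro = params.ring_radius_nm * e
    Lpro = params.procentriole_length_nm * e
    step = min(params.voxel_pitch_nm, params.voxel_pitch_z_nm) / 2.0

    emitters = _build_emitters(params)

    # procentriole local frame: z' radially outward, x' along the parent axis
    az = np.deg2rad(pa)
    zl = np.array([np.cos(az), np.sin(az), 0.0])
    xl = np.array([0.0, 0.0, 1.0])
    yl = np.cross(zl, xl)
    base_center = (Rpar + _PROCENTRIOLE_GAP_NM * e) * zl + np.array(
        [0.0, 0.0, -0.35 * Lpar])

    def local_to_canonical(pts_local):
        return base_center[None, :] + pts_local @ np.stack([xl, yl, zl])

    spacing = 360.0 / params.n_triplets
    pro_wall_pts, pro_wall_amps = [], []
    for k in range(params.n_triplets):
        b = np.deg2rad(pma + spacing * k)
        base = np.array([Rpro * np.cos(b), Rpro * np.sin(b), 0.0])
        pts, amps = _rod_points(base, np.array([0.0, 0.0, 1.0]), Lpro,
                                _WALL_DENSITY * params.intensity_scale, step)
        pro_wall_pts.append(local_to_canonical(pts))
        pro_wall_amps.append(amps)
    pro_wall = np.vstack(pro_wall_pts)

    lobe_az, lobe_amps = params.lobe_geometry()
    Rm = Rpro * params.marker_radius_fraction
    Lm = Lpro * params.marker_axial_fraction
    pro_mk_pts, pro_mk_amps = [], []
    for off, rel in zip((0.0, spacing), (1.0, 1.0 / params.marker_intensity_ratio)):
        b = np.deg2rad(pma + off)
        base = np.array([Rm * np.cos(b), Rm * np.sin(b), Lpro - Lm])
        pts, amps = _rod_points(base, np.array([0.0, 0.0, 1.0]), Lm,
                                _MARKER_DENSITY * rel * params.intensity_scale, step)
        pro_mk_pts.append(local_to_canonical(pts))
        pro_mk_amps.append(amps)

    wall_pts, wall_amps = emitters["wall"]
    overlap = False
    if len(wall_pts) and len(pro_wall):
        dmin = cKDTree(wall_pts).query(pro_wall, k=1)[0].min()
        overlap = bool(dmin < _CONTACT_TOL_NM * e)
    emitters["wall"] = (np.vstack([wall_pts, pro_wall]),
                        np.concatenate([wall_amps] + pro_wall_amps))
    mk_pts, mk_amps = emitters["marker"]
    emitters["marker"] = (np.vstack([mk_pts] + pro_mk_pts),
                          np.concatenate([mk_amps] + pro_mk_amps))

    volumes, origin, pitches, shape = _render(params, emitters)
    peak_locations = {}
    for role, v in volumes.items():
        z, y, x = np.unravel_index(int(np.argmax(v)), v.shape)
        peak_locations[role] = (float(x), float(y), float(z))
    rng = np.random.default_rng(params.seed)
    noisy = params.noise.apply(volumes, rng)
    roles = [r for r in ("wall", "marker", "reference", "appendage") if r in noisy]
    stack = ImageStack(
        voxels=np.stack([noisy[r] for r in roles]).astype(np.float32),
        voxel_pitch_nm=params.voxel_pitch_nm,
        voxel_pitch_z_nm=params.voxel_pitch_z_nm,
        channel_roles={i: r for i, r in enumerate(roles)},
        view_convention="distal",
    )
    pro_axis = params.pose.matrix() @ zl
    pro_axis = pro_axis / np.linalg.norm(pro_axis)
    truth = _ground_truth(params, origin, pitches, shape, peak_locations,
                          pro_azimuth=float(pa), pro_marker_azimuth=float(pma),
                          pro_axis=pro_axis, overlap=overlap)
    return stack, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class ParamJitter:
    """Per-parameter spread of a synthetic cohort.

    Defaults emulate a wild-type mother-centriole population: length SD
    56 nm, 10% ring-radius and marker-intensity spread, tilts uniform up to
    30 degrees off the imaging axis and in-plane rotation uniform on
    [0, 360).
    """

    length_sd_nm: float = 56.0
    radius_sd_frac: float = 0.10
    intensity_sd_frac: float = 0.10
    tilt_max_deg: float = 30.0
    translation_sd_nm: float = 30.0
    uniform_inplane: bool = True

    def validate(self):
        for name in ("length_sd_nm", "radius_sd_frac", "intensity_sd_frac",
                     "tilt_max_deg", "translation_sd_nm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @classmethod
    def near_perpendicular(cls, **overrides) -> "ParamJitter":
        """Acquisition-selected cohort: only nearly perpendicular particles.

        Averaging acquisitions keep centrioles within ~5 degrees of the
        imaging axis, because the anisotropic PSF smears tilted particles
        laterally and biases image-based reference azimuths.
        """
        kw = {"tilt_max_deg": 5.0}
        kw.update(overrides)
        return cls(**kw)


def particle_seed(master_seed: int, index: int) -> int:
    """Deterministic per-particle seed: SeedSequence([master, index])."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0] % (2**31))


def draw_cohort_params(base: GeneratorParams, n: int,
                       jitter: ParamJitter | None = None,
                       seed: int = 0) -> list:
    """The jittered parameter list of a cohort (no rendering)."""
    if n < 1:
        raise ParameterError("cohort size must be >= 1")
    jitter = jitter or ParamJitter()
    jitter.validate()
    out = []
    for i in range(n):
        s = particle_seed(seed, i)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(i), 1]))
        length = max(base.centriole_length_nm + rng.normal(0, jitter.length_sd_nm),
                     4 * base.ring_radius_nm * 0.2)
        radius = base.ring_radius_nm * (1 + rng.normal(0, jitter.radius_sd_frac))
        scale = max(base.intensity_scale * (1 + rng.normal(0, jitter.intensity_sd_frac)),
                    0.05)
        rot = rng.uniform(0, 360) if jitter.uniform_inplane else base.pose.rotation_deg
        tilt = rng.uniform(0, jitter.tilt_max_deg)
        tdir = rng.uniform(0, 360)
        trans = tuple(rng.normal(0, jitter.translation_sd_nm, 3) * (1, 1, 0))
        pose = Pose(tilt_deg=tilt, tilt_direction_deg=tdir, rotation_deg=rot,
                    translation_nm=trans)
        out.append(dataclasses.replace(
            base, centriole_length_nm=float(length), ring_radius_nm=float(radius),
            intensity_scale=float(scale), pose=pose, seed=s))
    return out


def generate_cohort(base: GeneratorParams, n: int,
                    jitter: ParamJitter | None = None, seed: int = 0) -> list:
    """n independent jittered particles; returns list of (stack, truth)."""
    return [generate_centriole(p) for p in draw_cohort_params(base, n, jitter, seed)]


# ---------------------------------------------------------------------------
# presets and auxiliary renders
# ---------------------------------------------------------------------------

def preset_centriole(**overrides) -> GeneratorParams:
    """Human-centrosome mother centriole with the two-lobe distal marker."""
    return dataclasses.replace(GeneratorParams(), **overrides)


def preset_mcc(**overrides) -> GeneratorParams:
    """Multiciliated-cell basal body: basal foot plus a three-triplet marker.

    The marker spans the peak triplet and both direct neighbours (triplets
    9, 1, 2 when numbered counterclockwise from the signal), and the basal
    foot sits opposite the marker, offset 25 degrees clockwise.
    """
    p = GeneratorParams(
        basal_foot_azimuth_offset_deg=25.0,
        marker_lobe_offsets_deg=(-40.0, 0.0, 40.0),
        marker_lobe_relative_amps=(0.5, 1.0, 0.7),
    )
    return dataclasses.replace(p, **overrides)


def preset_daughter(**overrides) -> GeneratorParams:
    """Daughter centriole: shorter wall, no appendage."""
    return dataclasses.replace(GeneratorParams(centriole_length_nm=320.0), **overrides)


PRESETS = {
    "centriole": preset_centriole,
    "mcc": preset_mcc,
    "daughter": preset_daughter,
}


def generate_interpeak_pair(offset_nm: float, expansion_factor: float = 1.0,
                            voxel_pitch_nm: float = 40.0,
                            voxel_pitch_z_nm: float = 150.0,
                            psf_sigma_nm: float = 90.0,
                            psf_sigma_z_nm: float = 250.0,
                            noise: NoiseModel | None = None,
                            seed: int = 0):
    """Diffraction-limited two-channel focus pair for interpeak-distance tests.

    Emulates the unexpanded-microscopy situation where the centriole appears
    as a single focus: the "center" channel holds a blob at the centriole
    position and the "marker" channel a blob displaced laterally (+x) by
    ``offset_nm`` pre-expansion nm, rendered at ``offset_nm * expansion``
    in the stack.  Returns (ImageStack, true_offset_nm).
    """
    off = offset_nm * expansion_factor
    margin = 3 * psf_sigma_nm + abs(off) + 4 * voxel_pitch_nm
    nx = int(np.ceil(2 * margin / voxel_pitch_nm)) | 1
    nz = int(np.ceil((6 * psf_sigma_z_nm) / voxel_pitch_z_nm)) | 1
    shape = (nz, nx, nx)
    c = np.array([(nx - 1) / 2 * voxel_pitch_nm, (nx - 1) / 2 * voxel_pitch_nm,
                  (nz - 1) / 2 * voxel_pitch_z_nm])
    pitches = np.array([voxel_pitch_nm, voxel_pitch_nm, voxel_pitch_z_nm])
    sigma_vox = (psf_sigma_z_nm / voxel_pitch_z_nm,
                 psf_sigma_nm / voxel_pitch_nm, psf_sigma_nm / voxel_pitch_nm)
    volumes = {}
    for role, shift in (("wall", 0.0), ("marker", off)):
        pt = (c + np.array([shift, 0.0, 0.0])) / pitches
        volumes[role] = gaussian_filter(
            _splat(pt[None, :], np.array([1000.0]), shape), sigma_vox)
    noise = noise or NoiseModel(peak_snr=None)
    noisy = noise.apply(volumes, np.random.default_rng(seed))
    stack = ImageStack(
        voxels=np.stack([noisy["wall"], noisy["marker"]]).astype(np.float32),
        voxel_pitch_nm=voxel_pitch_nm,
        voxel_pitch_z_nm=voxel_pitch_z_nm,
        channel_roles={0: "wall", 1: "marker"},
        view_convention="distal",
    )
    return stack, offset_nm
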