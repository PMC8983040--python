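"""Stack and annotation I/O.

Stacks travel as multi-page TIFF (channel-major pages) with a JSON sidecar
carrying voxel pitch, channel roles and view convention.  Annotations
travel as CSV (one row per particle, point lists JSON-encoded in their
cells) or as a JSON array; both are validated strictly, and every
rejection names the offending particle and field.

Coordinates in annotations are voxel-indexed, 0-based, (x, y, z) with x
the fastest axis.  ``ring_points`` and ``reference_point`` refer to the
verticalized stack; ``axis_points`` to the raw stack.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .stack import ImageStack

logger = logging.getLogger(__name__)

REFERENCE_MODES = ("point", "brightest", "basal_foot_point", "c_end_point", "none")


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page TIFF plus JSON sidecar; returns the path."""
    path = Path(path)
    v = stack.voxels
    tifffile.imwrite(path, v.reshape(-1, v.shape[2], v.shape[3]),
                     metadata=None, photometric="minisblack")
    meta = {
        "shape_czyx": list(v.shape),
        "dtype": str(v.dtype),
        "voxel_pitch_nm": stack.voxel_pitch_nm,
        "voxel_pitch_z_nm": stack.voxel_pitch_z_nm,
        "channel_roles": {str(k): r for k, r in stack.channel_roles.items()},
        "view_convention": stack.view_convention,
        "axes": "CZYX",
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def read_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_stack`.

    A TIFF without a sidecar loads with unknown pitch and every channel
    role marked "unknown"; downstream nm-valued operations then refuse it.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        shape = tuple(meta["shape_czyx"])
        if int(np.prod(shape)) != pages.size:
            raise ValidationError(
                f"{path}: page data of size {pages.size} does not match "
                f"sidecar shape {shape}")
        voxels = np.asarray(pages).reshape(shape)
        roles = {int(k): v for k, v in meta["channel_roles"].items()}
        return ImageStack(
            voxels=voxels,
            voxel_pitch_nm=meta.get("voxel_pitch_nm"),
            voxel_pitch_z_nm=meta.get("voxel_pitch_z_nm"),
            channel_roles=roles,
            view_convention=meta.get("view_convention", "distal"),
        )
    logger.warning("%s: no sidecar metadata; pitch unknown, roles unknown", path)
    v = np.asarray(pages)
    if v.ndim == 2:
        v = v[None, None]
    elif v.ndim == 3:
        v = v[None]
    return ImageStack(voxels=v, voxel_pitch_nm=None, voxel_pitch_z_nm=None,
                      channel_roles={c: "unknown" for c in range(v.shape[0])})


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class CentrioleAnnotation:
    """Per-centriole landmark record replacing interactive annotation.

    ring_points : (n >= 3, 2) voxel (x, y) on one transverse plane of the
        verticalized stack, outlining the triplet ring.
    reference_point : (x, y, z) voxel point for rotational registration;
        may be None when ``reference_mode`` is "brightest" or "none".
    axis_points : (2, 3) voxel points on the long axis of the raw stack,
        ordered proximal to distal.
    z_frame : (z_proximal, z_distal) plane coordinates bounding the
        centriole in the verticalized stack.
    """

    particle_id: str
    ring_points: np.ndarray
    reference_point: tuple | None
    axis_points: np.ndarray
    z_frame: tuple
    expansion_factor: float
    reference_mode: str = "point"
    view_convention: str = "distal"

    def __post_init__(self):
        self.ring_points = np.asarray(self.ring_points, dtype=float)
        self.axis_points = np.asarray(self.axis_points, dtype=float)
        self.validate()

    def validate(self) -> None:
        pid = self.particle_id

        def fail(fieldname, msg):
            raise ValidationError(f"annotation {pid!r}, field {fieldname}: {msg}")

        if self.ring_points.ndim != 2 or self.ring_points.shape[1] != 2:
            fail("ring_points", "must be an (n, 2) array")
        if len(self.ring_points) < 3:
            fail("ring_points", "ring_points >= 3 required")
        centered = self.ring_points - self.ring_points.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[0] == 0 or s[-1] / s[0] < 1e-6:
            fail("ring_points", "degenerate ring (collinear points)")
        if self.axis_points.shape != (2, 3):
            fail("axis_points", "must be two (x, y, z) points")
        if np.allclose(self.axis_points[0], self.axis_points[1]):
            fail("axis_points", "axis points coincide")
        if not self.z_frame[0] < self.z_frame[1]:
            fail("z_frame", f"z_proximal < z_distal required, got {self.z_frame}")
        if not self.expansion_factor > 1:
            fail("expansion_factor", "must be > 1")
        if self.reference_mode not in REFERENCE_MODES:
            fail("reference_mode", f"unknown mode {self.reference_mode!r}")
        if self.reference_mode in ("point", "basal_foot_point", "c_end_point"):
            if self.reference_point is None:
                fail("reference_point", f"required for mode {self.reference_mode!r}")
            if len(self.reference_point) != 3:
                fail("reference_point", "must be (x, y, z)")
        if self.view_convention not in ("distal", "proximal"):
            fail("view_convention", f"unknown {self.view_convention!r}")

    def axis_vector(self) -> np.ndarray:
        v = self.axis_points[1] - self.axis_points[0]
        return v / np.linalg.norm(v)

    def to_record(self) -> dict:
        return {
            "particle_id": self.particle_id,
            "ring_points": json.dumps(np.round(self.ring_points, 6).tolist()),
            "reference_point": json.dumps(
                None if self.reference_point is None
                else [round(float(c), 6) for c in self.reference_point]),
            "reference_mode": self.reference_mode,
            "axis_points": json.dumps(np.round(self.axis_points, 6).tolist()),
            "z_proximal": float(self.z_frame[0]),
            "z_distal": float(self.z_frame[1]),
            "expansion_factor": float(self.expansion_factor),
            "view_convention": self.view_convention,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "CentrioleAnnotation":
        pid = rec.get("particle_id", "<missing id>")
        try:
            ref = rec["reference_point"]
            if isinstance(ref, str):
                ref = json.loads(ref)
            ring = rec["ring_points"]
            if isinstance(ring, str):
                ring = json.loads(ring)
            axis = rec["axis_points"]
            if isinstance(axis, str):
                axis = json.loads(axis)
            if "z_frame" in rec:
                zf = tuple(rec["z_frame"])
            else:
                zf = (float(rec["z_proximal"]), float(rec["z_distal"]))
            return cls(
                particle_id=str(pid),
                ring_points=ring,
                reference_point=None if ref is None else tuple(ref),
                reference_mode=rec.get("reference_mode", "point"),
                axis_points=axis,
                z_frame=zf,
                expansion_factor=float(rec["expansion_factor"]),
                view_convention=rec.get("view_convention", "distal"),
            )
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise ValidationError(
                f"annotation {pid!r}: malformed record ({exc})") from exc


def save_annotations(annotations, path) -> Path:
    """Write annotations as CSV (``.csv``) or a JSON array (anything else)."""
    path = Path(path)
    records = [a.to_record() for a in annotations]
    if path.suffix == ".csv":
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    return path


def load_annotations(path) -> list:
    """Load and validate annotations from CSV or JSON."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"annotation file not found: {path}")
    if path.suffix == ".csv":
        records = pd.read_csv(path).to_dict("records")
    else:
        with open(path) as fh:
            records = json.load(fh)
    return [CentrioleAnnotation.from_record(r) for r in records]


def write_cohort_index(truths, path, particle_ids=None) -> Path:
    """Cohort-level CSV index of ground truths (one row per particle)."""
    path = Path(path)
    rows = []
    for i, t in enumerate(truths):
        pid = particle_ids[i] if particle_ids is not None else f"particle_{i:04d}"
        rows.append({
            "particle_id": pid,
            "marker_azimuth_deg": t.params.marker_azimuth_deg,
            "marker_centroid_azimuth_deg": t.marker_centroid_azimuth_deg,
            "procentriole_azimuth_deg": t.procentriole_azimuth_deg,
            "length_nm": t.params.centriole_length_nm,
            "expansion_factor": t.params.expansion_factor,
            "seed": t.params.seed,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
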