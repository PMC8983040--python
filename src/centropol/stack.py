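"""The in-memory voxel container shared by the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: channel role labels understood by the pipeline
ROLES = ("wall", "marker", "reference", "appendage", "unknown")


@dataclass
class ImageStack:
    """Multichannel 3D fluorescence volume.

    Attributes
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Non-negative intensities. x is the fastest axis.
    voxel_pitch_nm : float or None
        Lateral (y and x) voxel size in expanded-space nanometres. ``None``
        marks the pitch as unknown; nm-valued operations refuse such stacks.
    voxel_pitch_z_nm : float or None
        Axial voxel size; may differ from the lateral pitch.
    channel_roles : dict
        Channel index -> role label ("wall", "marker", "reference",
        "appendage", "unknown").
    view_convention : str
        "distal" (observer at the distal end; counterclockwise azimuths are
        mathematically positive) or "proximal" (mirror image: azimuth signs
        flip). The distal end always sits at the larger z index.
    """

    voxels: np.ndarray
    voxel_pitch_nm: float | None = None
    voxel_pitch_z_nm: float | None = None
    channel_roles: dict = field(default_factory=dict)
    view_convention: str = "distal"

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 4:
            raise ValidationError(f"voxels must be 4-D (C,Z,Y,X), got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("voxels contain non-finite values")
        if v.size and float(v.min()) < 0:
            raise ValidationError("voxels contain negative intensities")
        if self.voxel_pitch_nm is not None and self.voxel_pitch_nm <= 0:
            raise ValidationError("voxel_pitch_nm must be > 0")
        if self.voxel_pitch_z_nm is not None and self.voxel_pitch_z_nm <= 0:
            raise ValidationError("voxel_pitch_z_nm must be > 0")
        if self.view_convention not in ("distal", "proximal"):
            raise ValidationError(f"unknown view_convention {self.view_convention!r}")
        self.voxels = v
        if not self.channel_roles:
            self.channel_roles = {c: "unknown" for c in range(v.shape[0])}

    # -- convenience -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple:
        return self.voxels.shape[1:]

    def channel(self, role_or_index) -> np.ndarray:
        """Channel volume (Z, Y, X) selected by role label or integer index."""
        return self.voxels[self.channel_index(role_or_index)]

    def channel_index(self, role_or_index) -> int:
        if isinstance(role_or_index, (int, np.integer)):
            idx = int(role_or_index)
            if not 0 <= idx < self.n_channels:
                raise ValidationError(f"channel index {idx} out of range")
            return idx
        for idx, role in self.channel_roles.items():
            if role == role_or_index:
                return int(idx)
        raise ValidationError(f"no channel with role {role_or_index!r}")

    def require_pitch(self) -> tuple:
        from .errors import MeasurementError

        if self.voxel_pitch_nm is None or self.voxel_pitch_z_nm is None:
            raise MeasurementError(
                "operation needs a physical voxel pitch, but the stack's pitch is unknown"
            )
        return float(self.voxel_pitch_nm), float(self.voxel_pitch_z_nm)

    def azimuth_sign(self) -> float:
        """+1 in distal view, -1 in proximal view (chirality of azimuths)."""
        return 1.0 if self.view_convention == "distal" else -1.0
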