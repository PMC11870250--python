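"""Core containers for 4D flow velocity datasets.

Internal unit conventions, used everywhere in this package:

* velocity        cm/s (vector components expressed in world axes)
* geometry        mm (voxel spacing, world coordinates, plane offsets)
* time            ms (frame duration ``dt``)
* flow rate       mL/s
* momentum rate   mN
* regurgitant volume  mL, time-integrated momentum  mN·s

Converters live only at the I/O boundary (:mod:`jetquant.io`).  Voxel
indices are 0-based; the affine maps voxel indices to world millimetres,
so all plane geometry can be done in world space regardless of voxel
anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class FlowStudy:
    """A 4D flow dataset: three-directional velocities over a volume and time.

    Parameters
    ----------
    velocity:
        Array of shape ``(X, Y, Z, T, 3)`` in cm/s.  The last axis holds the
        velocity vector components along the *world* axes.
    magnitude:
        Signal magnitude, shape ``(X, Y, Z, T)``, arbitrary units.
    spacing:
        Voxel edge lengths in mm, one per spatial axis.
    dt:
        Frame duration in ms.
    venc:
        Velocity-encoding limit in cm/s; components beyond ±venc alias.
    affine:
        4x4 matrix mapping homogeneous 0-based voxel indices to world mm.
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    spacing: np.ndarray
    dt: float
    venc: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise ValidationError(
                f"velocity must have shape (X, Y, Z, T, 3), got {self.velocity.shape}"
            )
        if self.magnitude.shape != self.velocity.shape[:4]:
            raise ValidationError(
                "magnitude shape "
                f"{self.magnitude.shape} does not match velocity grid "
                f"{self.velocity.shape[:4]}"
            )
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not self.dt > 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if not self.venc > 0:
            raise ValidationError(f"venc must be positive, got {self.venc}")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine must be an invertible 4x4 matrix")

    # -- geometry ---------------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[3]

    @property
    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def world_from_voxel(self, idx: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices (may be fractional) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_from_world(self, world: np.ndarray) -> np.ndarray:
        """Map (…, 3) world-mm positions to fractional voxel indices."""
        world = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        return world @ inv[:3, :3].T + inv[:3, 3]

    def speed(self, t: int | None = None) -> np.ndarray:
        """Velocity vector norm, cm/s; one frame if ``t`` is given."""
        v = self.velocity if t is None else self.velocity[..., t, :]
        return np.linalg.norm(v, axis=-1)


@dataclass
class ChamberMask:
    """Binary mask of the receiving chamber on a study's voxel grid."""

    mask: np.ndarray
    label: str = "LA"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValidationError(f"mask must be 3D, got shape {self.mask.shape}")
        if not self.mask.any():
            raise ValidationError("chamber mask is empty (no true voxels)")

    def check_against(self, study: FlowStudy) -> None:
        if self.mask.shape != study.grid_shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match study grid {study.grid_shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ScalarVolume:
    """A 3D scalar field sharing a study's affine (e.g. a PC-MRA)."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("scalar volume contains non-finite values")


def compute_pcmra(study: FlowStudy) -> ScalarVolume:
    """Phase-contrast MR angiogram: time-average of speed × signal magnitude.

    Bright voxels mark coherent flow, which is what chamber segmentation and
    jet localisation key on.  The result is non-negative by construction.
    """
    speed = np.linalg.norm(study.velocity, axis=-1)
    values = np.mean(speed * study.magnitude, axis=-1)
    return ScalarVolume(values=values, affine=study.affine)
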