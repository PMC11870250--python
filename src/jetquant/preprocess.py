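"""Velocity preprocessing: background phase-offset and aliasing correction.

Phase-contrast velocities carry a slowly varying background offset (eddy
currents, concomitant gradients) and may wrap when the true velocity
exceeds the encoding limit.  Both corrections operate voxel-wise on the
velocity array and report what they did.

Offset model: a second-order 3D polynomial per velocity component, fitted
by least squares to the time-averaged velocity over static-tissue voxels
(temporal speed SD and mean speed both below a threshold, default 5 cm/s)
and subtracted from every frame.  Aliasing: temporal phase unwrapping with
period 2·VENC followed by recentering of each voxel's time series; a wrap
that is constant over the whole series leaves no temporal jump and is not
detectable by this (or any temporal) method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import FlowStudy

N_POLY_COEFFS = 10  # 1, x, y, z, x², y², z², xy, xz, yz
MIN_STATIC_FACTOR = 3  # require at least 3x coefficients worth of voxels


@dataclass
class PreprocessReport:
    offset_coefficients: np.ndarray | None = None   # (3, 10), world-mm basis
    static_voxel_count: int = 0
    insufficient_static_tissue: bool = False
    unwrapped_per_frame: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def unwrapped_total(self) -> int:
        return int(self.unwrapped_per_frame.sum())


def _design_matrix(world_mm: np.ndarray) -> np.ndarray:
    x, y, z = world_mm[:, 0], world_mm[:, 1], world_mm[:, 2]
    return np.stack([np.ones_like(x), x, y, z, x * x, y * y, z * z,
                     x * y, x * z, y * z], axis=1)


def correct_phase_offset(study: FlowStudy, static_threshold_cm_s: float = 5.0
                         ) -> tuple[FlowStudy, PreprocessReport]:
    """Fit and subtract the static-tissue background offset field.

    If fewer static voxels than ``3 × 10`` coefficients are available the
    study is returned unchanged with a warning flag in the report.
    """
    if static_threshold_cm_s <= 0:
        raise ValueError("static_threshold_cm_s must be positive")
    speed = study.speed()                             # (X, Y, Z, T)
    static = ((speed.std(axis=-1) < static_threshold_cm_s)
              & (speed.mean(axis=-1) < static_threshold_cm_s))
    n_static = int(static.sum())
    if n_static < MIN_STATIC_FACTOR * N_POLY_COEFFS:
        return study, PreprocessReport(static_voxel_count=n_static,
                                       insufficient_static_tissue=True)

    idx = np.argwhere(static).astype(float)
    world_static = study.world_from_voxel(idx)
    A = _design_matrix(world_static)

    mean_v = study.velocity.mean(axis=3)              # (X, Y, Z, 3)
    coeffs = np.zeros((3, N_POLY_COEFFS))
    for c in range(3):
        coeffs[c], *_ = np.linalg.lstsq(A, mean_v[..., c][static], rcond=None)

    # evaluate the fitted offset on the full grid and subtract from all frames
    nx, ny, nz = study.grid_shape
    grid_idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                    indexing="ij"), axis=-1).reshape(-1, 3)
    A_full = _design_matrix(study.world_from_voxel(grid_idx.astype(float)))
    corrected = study.velocity.copy()
    for c in range(3):
        offset = (A_full @ coeffs[c]).reshape(nx, ny, nz)
        corrected[..., c] -= offset[..., None]

    out = replace(study, velocity=corrected)
    return out, PreprocessReport(offset_coefficients=coeffs,
                                 static_voxel_count=n_static)


def unwrap_aliasing(study: FlowStudy) -> tuple[FlowStudy, PreprocessReport]:
    """Temporally unwrap velocity components that jump by more than VENC
    between adjacent frames (period 2·VENC), then recenter each voxel's
    series so no component exceeds 2.5×VENC in magnitude."""
    venc = study.venc
    v = study.velocity
    unwrapped = np.unwrap(v, axis=3, period=2.0 * venc)
    # Recenter only series the unwrap touched AND drove beyond 2.5×VENC
    # (multi-wrap drift): a wrap constant over the whole series leaves no
    # temporal jump and must stay as-is, and legitimately encoded series
    # must not be shifted.
    touched = np.any(~np.isclose(unwrapped, v, rtol=0, atol=1e-9 * venc),
                     axis=3, keepdims=True)
    excessive = np.max(np.abs(unwrapped), axis=3, keepdims=True) > 2.5 * venc
    median = np.median(unwrapped, axis=3, keepdims=True)
    shift = np.where(touched & excessive,
                     2.0 * venc * np.round(median / (2.0 * venc)), 0.0)
    unwrapped = unwrapped - shift
    changed = ~np.isclose(unwrapped, v, rtol=0, atol=1e-9 * venc)
    per_frame = changed.any(axis=-1).sum(axis=(0, 1, 2))
    out = replace(study, velocity=unwrapped)
    return out, PreprocessReport(unwrapped_per_frame=np.asarray(per_frame))
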