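"""Measurement-plane placement along the jet axis.

Implements the tracked-plane geometry of the direct quantification method:
the regurgitant interval is found from chamber velocities, the central plane
is centered on the frame-wise peak-velocity voxel inside the receiving
chamber, its normal is the component-wise median of the 3×3×3 velocity
neighbourhood (so the plane is perpendicular to the jet), and three further
planes are stacked 2.5 mm apart on either side, each re-oriented at its own
location.  Through-plane velocity maps are resampled on a 0.5 mm pixel grid
by trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as ndi_label
from scipy.ndimage import map_coordinates

from .datamodel import ChamberMask, FlowStudy

DEFAULT_PLANE_OFFSETS_MM = np.arange(-3, 4) * 2.5   # −7.5 … +7.5 mm


class NoJetError(RuntimeError):
    """No frame shows chamber velocities above the jet threshold."""


class DegenerateNormalError(RuntimeError):
    """The median neighbourhood velocity vector has zero length."""


@dataclass
class MRInterval:
    """First and last frame index (inclusive) of the regurgitant interval."""

    t0: int
    t_end: int

    def __post_init__(self) -> None:
        if not 0 <= self.t0 <= self.t_end:
            raise ValueError(f"invalid interval ({self.t0}, {self.t_end})")

    @property
    def frames(self) -> range:
        return range(self.t0, self.t_end + 1)


@dataclass
class JetPlane:
    """An oriented, bounded sampling plane at axial offset x from the
    tracked reference point."""

    center_mm: np.ndarray       # world mm
    normal: np.ndarray          # unit vector, world
    offset_mm: float            # signed axial offset x
    basis_u: np.ndarray         # in-plane orthonormal basis
    basis_v: np.ndarray
    extent_mm: float = 20.0     # half-width of the square sampling window
    pitch_mm: float = 0.5
    usable: bool = True

    @property
    def pixel_area_mm2(self) -> float:
        return self.pitch_mm ** 2


@dataclass
class ThroughPlaneMap:
    """Through-plane velocity image V⊥ on a plane's pixel grid.

    Positive values flow along the plane normal.  ``outside`` flags pixels
    that fell outside the acquired volume (their V⊥ is zero).
    """

    values: np.ndarray          # (n, n), cm/s
    plane: JetPlane
    frame: int
    outside: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.outside is None:
            self.outside = np.zeros(self.values.shape, dtype=bool)

    @property
    def pixel_area_mm2(self) -> float:
        return self.plane.pixel_area_mm2

    @property
    def center_index(self) -> tuple[int, int]:
        return self.values.shape[0] // 2, self.values.shape[1] // 2

    @property
    def center_velocity(self) -> float:
        return float(self.values[self.center_index])


# -- step 1: regurgitant interval -----------------------------------------

def detect_mr_interval(study: FlowStudy, mask: ChamberMask,
                       speed_threshold_cm_s: float = 100.0,
                       override: tuple[int, int] | None = None) -> MRInterval:
    """Longest contiguous run of frames whose peak in-chamber speed exceeds
    the threshold.  ``override`` bypasses detection (the manual route)."""
    if override is not None:
        return MRInterval(int(override[0]), int(override[1]))
    mask.check_against(study)
    peak = np.array([study.speed(t)[mask.mask].max() for t in range(study.n_frames)])
    active = peak > speed_threshold_cm_s
    if not active.any():
        raise NoJetError(
            f"no frame exceeds {speed_threshold_cm_s:g} cm/s inside the chamber")
    best, run_start, best_len = (0, 0), None, 0
    for t, a in enumerate([*active, False]):
        if a and run_start is None:
            run_start = t
        elif not a and run_start is not None:
            if t - run_start > best_len:
                best, best_len = (run_start, t - 1), t - run_start
            run_start = None
    return MRInterval(*best)


# -- step 2: peak-velocity tracking ---------------------------------------

def find_peak_velocity_voxel(study: FlowStudy, mask: ChamberMask, t: int,
                             prev_peak: tuple[int, int, int] | None = None,
                             seed_world_mm: np.ndarray | None = None,
                             seed_region_fraction: float = 0.2
                             ) -> tuple[int, int, int]:
    """In-chamber voxel with maximal speed at frame ``t``.

    Ties are broken by proximity to the previous frame's peak (first frame:
    smallest linear index).  An optional seed point confines the search to
    the 26-connected high-speed region (>= ``seed_region_fraction`` of the
    frame maximum) containing it — the automated stand-in for manually
    confirming that the voxel lies within the jet of interest.
    """
    mask.check_against(study)
    speed = study.speed(t)
    search = mask.mask.copy()
    if seed_world_mm is not None:
        frame_max = speed[mask.mask].max()
        high = (speed >= seed_region_fraction * frame_max) & mask.mask
        labels, _ = ndi_label(high, structure=np.ones((3, 3, 3), dtype=int))
        seed_idx = np.clip(np.round(study.voxel_from_world(seed_world_mm)).astype(int),
                           0, np.array(study.grid_shape) - 1)
        seed_label = labels[tuple(seed_idx)]
        if seed_label == 0:  # seed off the jet: fall back to nearest labelled voxel
            cand = np.argwhere(labels > 0)
            seed_label = labels[tuple(cand[np.argmin(
                np.linalg.norm(cand - seed_idx, axis=1))])]
        search &= labels == seed_label
    masked = np.where(search, speed, -np.inf)
    vmax = masked.max()
    if not np.isfinite(vmax):
        raise NoJetError("empty search region for peak-velocity voxel")
    candidates = np.argwhere(masked == vmax)
    if len(candidates) > 1 and prev_peak is not None:
        d = np.linalg.norm((candidates - np.asarray(prev_peak)) *
                           study.spacing, axis=1)
        return tuple(int(v) for v in candidates[np.argmin(d)])
    return tuple(int(v) for v in candidates[0])


# -- step 3: plane orientation --------------------------------------------

def estimate_plane_normal(study: FlowStudy, center_voxel: tuple[int, int, int],
                          t: int, min_speed_cm_s: float = 1e-9) -> np.ndarray:
    """Component-wise median of the 3×3×3 neighbourhood velocity vectors,
    normalised; sign aligned with the center voxel's velocity.

    ``min_speed_cm_s`` rejects medians whose magnitude is too small to define
    a reliable jet direction (used when re-orienting off-center planes whose
    centers may fall outside the jet)."""
    i, j, k = center_voxel
    nx, ny, nz = study.grid_shape
    sl = (slice(max(i - 1, 0), min(i + 2, nx)),
          slice(max(j - 1, 0), min(j + 2, ny)),
          slice(max(k - 1, 0), min(k + 2, nz)))
    neighbourhood = study.velocity[sl][..., t, :].reshape(-1, 3)
    med = np.median(neighbourhood, axis=0)
    norm = np.linalg.norm(med)
    if norm < min_speed_cm_s:
        raise DegenerateNormalError(
            f"median velocity at voxel {center_voxel}, frame {t} too weak "
            f"({norm:.3g} cm/s) to define a plane normal")
    normal = med / norm
    if normal @ study.velocity[i, j, k, t, :] < 0:
        normal = -normal
    return normal


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane orthonormal basis: cross the normal with the
    world axis of its smallest absolute component."""
    axis = np.zeros(3)
    axis[np.argmin(np.abs(normal))] = 1.0
    u = np.cross(normal, axis)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


# -- step 4: plane fan ----------------------------------------------------

def place_planes(study: FlowStudy, center_mm: np.ndarray, normal: np.ndarray,
                 t: int, spacing_mm: float = 2.5, count: int = 7,
                 extent_mm: float = 20.0, pitch_mm: float = 0.5,
                 reorient_min_speed_cm_s: float = 10.0) -> list[JetPlane]:
    """Stack ``count`` (odd) planes ``spacing_mm`` apart along the central
    normal.  Each off-center plane's normal is re-estimated at its own
    center, oriented along the central normal, and falls back to the central
    normal where the local flow is too weak (< ``reorient_min_speed_cm_s``)
    to define a direction; planes whose center leaves the grid are flagged
    unusable, never dropped."""
    if count % 2 == 0:
        raise ValueError("plane count must be odd")
    if spacing_mm <= 0:
        raise ValueError("plane spacing must be positive")
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    center_mm = np.asarray(center_mm, dtype=float)
    half = count // 2
    offsets = (np.arange(count) - half) * spacing_mm
    grid_hi = np.array(study.grid_shape) - 1
    planes = []
    for x in offsets:
        c = center_mm + x * normal
        vox = study.voxel_from_world(c)
        usable = bool(np.all(vox >= 0) and np.all(vox <= grid_hi))
        n = normal
        if usable and x != 0:
            nearest = tuple(np.clip(np.round(vox).astype(int), 0, grid_hi))
            try:
                n = estimate_plane_normal(study, nearest, t,
                                          min_speed_cm_s=reorient_min_speed_cm_s)
            except DegenerateNormalError:
                n = normal
            if n @ normal < 0:   # all planes face along the jet axis
                n = -n
        u, v = _plane_basis(n)
        planes.append(JetPlane(center_mm=c, normal=n, offset_mm=float(x),
                               basis_u=u, basis_v=v, extent_mm=extent_mm,
                               pitch_mm=pitch_mm, usable=usable))
    return planes


# -- step 5: through-plane reformat ---------------------------------------

def reformat_throughplane(study: FlowStudy, plane: JetPlane, t: int
                          ) -> ThroughPlaneMap:
    """Trilinearly interpolate the velocity vectors on the plane's pixel
    grid and project onto the plane normal.  Pixels outside the volume are
    zero and flagged."""
    n_half = int(round(plane.extent_mm / plane.pitch_mm))
    coords_1d = (np.arange(2 * n_half + 1) - n_half) * plane.pitch_mm
    a, b = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    world = (plane.center_mm
             + a[..., None] * plane.basis_u
             + b[..., None] * plane.basis_v)
    vox = study.voxel_from_world(world)

    grid_hi = np.array(study.grid_shape, dtype=float) - 1
    outside = np.any((vox < 0) | (vox > grid_hi), axis=-1)

    coords = [vox[..., 0].ravel(), vox[..., 1].ravel(), vox[..., 2].ravel()]
    vperp = np.zeros(a.shape)
    for c in range(3):
        comp = map_coordinates(study.velocity[..., t, c], coords, order=1,
                               mode="constant", cval=0.0).reshape(a.shape)
        vperp += comp * plane.normal[c]
    vperp[outside] = 0.0
    return ThroughPlaneMap(values=vperp, plane=plane, frame=t, outside=outside)
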