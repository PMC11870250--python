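"""Dual-velocity contouring of the jet region on through-plane maps.

The jet region Ω_jet is grown in two stages: an isovelocity core at 20% of
the plane-center velocity captures the jet's shape, then the core is
radially dilated, admitting only pixels above the absolute 10 cm/s
isovelocity bound with the same flow direction as the center, until no
admissible pixel remains.  Growth never crosses a sign change, so the
automatic contour cannot leak into counter-directional chamber inflow.
Manual edits may subsequently add or remove pixels as long as the region
stays connected and keeps its center.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import binary_dilation, label as ndi_label

from .planes import ThroughPlaneMap

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)

DEFAULT_INNER_FRACTION = 0.2       # core threshold as fraction of |V_center|
DEFAULT_OUTER_CM_S = 10.0          # absolute jet boundary, 0.1 m/s


class ContourEditError(ValueError):
    """An edit would disconnect the region or remove its center."""


@dataclass
class JetContour:
    """Pixel set Ω_jet on a through-plane map."""

    pixels: np.ndarray                 # boolean (n, n)
    center: tuple[int, int]
    inner_threshold_cm_s: float
    outer_threshold_cm_s: float
    touched_plane_boundary: bool = False
    manually_edited: bool = False
    empty_reason: str | None = None

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    def area_mm2(self, pixel_area_mm2: float) -> float:
        return self.n_pixels * pixel_area_mm2


def _component_containing(mask: np.ndarray, seed: tuple[int, int],
                          structure: np.ndarray) -> np.ndarray:
    labels, _ = ndi_label(mask, structure=structure)
    lab = labels[seed]
    if lab == 0:
        return np.zeros_like(mask)
    return labels == lab


def dual_velocity_contour(tpm: ThroughPlaneMap,
                          inner_fraction: float = DEFAULT_INNER_FRACTION,
                          outer_cm_s: float = DEFAULT_OUTER_CM_S) -> JetContour:
    """Contour the jet region on a through-plane velocity image.

    Returns an empty contour (with a reason) when the plane-center velocity
    is below the outer threshold — there is no jet at this plane and frame.
    """
    center = tpm.center_index
    vc = tpm.values[center]
    inner_thr = inner_fraction * abs(vc)
    if abs(vc) < outer_cm_s:
        return JetContour(pixels=np.zeros(tpm.values.shape, dtype=bool),
                          center=center, inner_threshold_cm_s=inner_thr,
                          outer_threshold_cm_s=outer_cm_s,
                          empty_reason="center below outer threshold")

    sign = 1.0 if vc > 0 else -1.0
    signed = sign * tpm.values

    # stage 1: isovelocity core at 20% of the center velocity (clipped to
    # the outer bound so every member respects the 10 cm/s jet boundary)
    core = _component_containing(signed >= max(inner_thr, outer_cm_s), center,
                                 FOUR_CONNECTED)
    if not core.any():
        core = np.zeros(tpm.values.shape, dtype=bool)
        core[center] = True

    # stage 2: dilate, admitting only same-signed pixels above the outer
    # isovelocity bound, until nothing more is admissible
    admissible = signed >= outer_cm_s
    region = core
    while True:
        grown = binary_dilation(region, structure=EIGHT_CONNECTED) & (admissible | region)
        if np.array_equal(grown, region):
            break
        region = grown

    # Ω_jet is a single 4-connected component containing the center
    region = _component_containing(region, center, FOUR_CONNECTED)

    edge = np.zeros_like(region)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    return JetContour(pixels=region, center=center,
                      inner_threshold_cm_s=inner_thr,
                      outer_threshold_cm_s=outer_cm_s,
                      touched_plane_boundary=bool((region & edge).any()))


def edit_contour(contour: JetContour,
                 add: set[tuple[int, int]] = frozenset(),
                 remove: set[tuple[int, int]] = frozenset()) -> JetContour:
    """Apply a manual correction.  Rejects edits that remove the center or
    disconnect the region; a no-op edit leaves the edited flag unset."""
    add, remove = set(add), set(remove)
    if not add and not remove:
        return replace(contour, pixels=contour.pixels.copy())
    if contour.center in remove:
        raise ContourEditError("cannot remove the contour center pixel")
    pixels = contour.pixels.copy()
    for ij in add:
        pixels[ij] = True
    for ij in remove:
        pixels[ij] = False
    if not pixels[contour.center]:
        raise ContourEditError("edited region no longer contains the center")
    component = _component_containing(pixels, contour.center, FOUR_CONNECTED)
    if not np.array_equal(component, pixels):
        raise ContourEditError("edit disconnects the jet region")
    return replace(contour, pixels=pixels, manually_edited=True)


# -- serialisation ---------------------------------------------------------

def rle_encode(pixels: np.ndarray) -> np.ndarray:
    """Run-length encode a boolean mask as (start, length) pairs over the
    flattened array."""
    flat = pixels.ravel()
    padded = np.concatenate([[False], flat, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[::2], changes[1::2]
    return np.stack([starts, ends - starts], axis=1).astype(np.int64)


def rle_decode(runs: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in np.asarray(runs, dtype=int):
        flat[start:start + length] = True
    return flat.reshape(shape)
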