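"""Readers and writers for 4D flow studies and chamber masks.

Two on-disk dialects are supported:

* **HDF5** (lossless native container): datasets ``/velocity`` float32 with
  shape (X, Y, Z, T, 3) and ``/magnitude`` float32 (X, Y, Z, T); attributes
  ``spacing`` (3,), ``dt``, ``venc``, ``affine`` (4, 4), and optionally
  ``velocity_units``.  A boolean ``/mask`` dataset may ride along.
* **NIfTI** for interoperability: a quadruplet of 4D files
  ``<prefix>_vx/_vy/_vz/_mag.nii.gz`` or a single 5D file (component last)
  plus ``<prefix>_mag``.  ``venc``, ``dt`` and the velocity units are encoded
  in the header ``descrip`` field as ``units=cm/s;venc=200;dt=38.4``.

Whatever the declared on-disk units, loaded studies are converted to the
package-internal cm/s and mm.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .datamodel import ChamberMask, FlowStudy, ValidationError

_COMPONENT_SUFFIXES = ("_vx", "_vy", "_vz")
_UNIT_TO_CM_S = {"cm/s": 1.0, "m/s": 100.0, "mm/s": 0.1}


def _strip_nifti_ext(path: str | Path) -> str:
    """Reduce any quadruplet member (or bare prefix) to the common prefix."""
    s = str(path)
    for ext in (".nii.gz", ".nii"):
        if s.endswith(ext):
            s = s[: -len(ext)]
            break
    for suffix in (*_COMPONENT_SUFFIXES, "_mag"):
        if s.endswith(suffix):
            return s[: -len(suffix)]
    return s


def _infer_format(path: str | Path) -> str:
    s = str(path)
    if s.endswith((".h5", ".hdf5")):
        return "hdf5"
    return "nifti"


def save_flow_study(study: FlowStudy, path: str | Path, format: str | None = None,
                    mask: ChamberMask | None = None) -> None:
    """Write a study to disk.  HDF5 round-trips bit-identically (float32);
    NIfTI round-trips within float32 precision."""
    fmt = format or _infer_format(path)
    try:
        if fmt == "hdf5":
            _save_hdf5(study, path, mask)
        elif fmt == "nifti":
            _save_nifti(study, path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except OSError as exc:
        raise OSError(f"failed to write flow study to {path}: {exc}") from exc


def load_flow_study(path: str | Path, format: str | None = None) -> FlowStudy:
    """Read a study written by :func:`save_flow_study` (or compatible)."""
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return _load_hdf5(path)
    if fmt == "nifti":
        return _load_nifti(path)
    raise ValueError(f"unknown format {format!r}")


# -- HDF5 dialect ---------------------------------------------------------

def _save_hdf5(study: FlowStudy, path, mask: ChamberMask | None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=study.velocity.astype(np.float32),
                         track_times=False)
        f.create_dataset("magnitude", data=study.magnitude.astype(np.float32),
                         track_times=False)
        if mask is not None:
            f.create_dataset("mask", data=mask.mask.astype(np.uint8),
                             track_times=False)
            f["mask"].attrs["label"] = mask.label
        f.attrs["spacing"] = study.spacing
        f.attrs["dt"] = study.dt
        f.attrs["venc"] = study.venc
        f.attrs["affine"] = study.affine
        f.attrs["velocity_units"] = "cm/s"


def _load_hdf5(path) -> FlowStudy:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such flow study: {path}")
    with h5py.File(path, "r") as f:
        for name in ("velocity", "magnitude"):
            if name not in f:
                raise ValidationError(f"{path}: missing dataset /{name}")
        vel = f["velocity"][...].astype(float)
        mag = f["magnitude"][...].astype(float)
        units = str(f.attrs.get("velocity_units", "cm/s"))
        missing = [k for k in ("spacing", "dt", "venc", "affine") if k not in f.attrs]
        if missing:
            raise ValidationError(f"{path}: missing attributes {missing}")
        vel *= _UNIT_TO_CM_S.get(units, 1.0)
        return FlowStudy(velocity=vel, magnitude=mag,
                         spacing=np.array(f.attrs["spacing"]),
                         dt=float(f.attrs["dt"]), venc=float(f.attrs["venc"]),
                         affine=np.array(f.attrs["affine"]))


# -- NIfTI dialect --------------------------------------------------------

def _descrip(study: FlowStudy) -> bytes:
    return f"units=cm/s;venc={study.venc:g};dt={study.dt:g}".encode()


def _parse_descrip(descrip: bytes) -> dict:
    out = {}
    text = descrip.decode(errors="ignore").replace("\x00", "")
    for key, val in re.findall(r"(\w+/?\w*)=([^;]+)", text):
        out[key] = val
    return out


def _save_nifti(study: FlowStudy, path) -> None:
    prefix = _strip_nifti_ext(path)
    descrip = _descrip(study)
    for c, suffix in enumerate(_COMPONENT_SUFFIXES):
        img = nib.Nifti1Image(study.velocity[..., c].astype(np.float32), study.affine)
        img.header["descrip"] = descrip
        nib.save(img, f"{prefix}{suffix}.nii.gz")
    img = nib.Nifti1Image(study.magnitude.astype(np.float32), study.affine)
    img.header["descrip"] = descrip
    nib.save(img, f"{prefix}_mag.nii.gz")


def _find_nifti(prefix: str, suffix: str) -> str:
    for ext in (".nii.gz", ".nii"):
        candidate = f"{prefix}{suffix}{ext}"
        if os.path.exists(candidate):
            return candidate
    raise FileNotFoundError(f"missing NIfTI component file {prefix}{suffix}.nii[.gz]")


def _load_nifti(path) -> FlowStudy:
    prefix = _strip_nifti_ext(path)
    five_d = None
    if os.path.exists(path) and str(path) != prefix + "_mag.nii.gz":
        img = nib.load(str(path))
        if img.ndim == 5:
            five_d = img

    if five_d is not None:
        vel = np.asarray(five_d.dataobj, dtype=float)
        if vel.shape[-1] != 3:
            raise ValidationError(f"{path}: 5D NIfTI last axis must be 3, got {vel.shape[-1]}")
        header_img = five_d
    else:
        comps = []
        for suffix in _COMPONENT_SUFFIXES:
            img = nib.load(_find_nifti(prefix, suffix))
            comps.append(np.asarray(img.dataobj, dtype=float))
        header_img = img
        shapes = {c.shape for c in comps}
        if len(shapes) != 1:
            raise ValidationError(f"velocity component shapes disagree: {sorted(shapes)}")
        vel = np.stack(comps, axis=-1)

    mag_img = nib.load(_find_nifti(prefix, "_mag"))
    mag = np.asarray(mag_img.dataobj, dtype=float)
    if mag.shape != vel.shape[:4]:
        raise ValidationError(
            f"magnitude shape {mag.shape} does not match velocity grid {vel.shape[:4]}"
        )

    meta = _parse_descrip(bytes(header_img.header["descrip"].tobytes()))
    if "venc" not in meta or "dt" not in meta:
        raise ValidationError(f"{path}: NIfTI descrip lacks venc/dt metadata")
    vel *= _UNIT_TO_CM_S.get(meta.get("units", "cm/s"), 1.0)
    affine = np.asarray(header_img.affine, dtype=float)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    return FlowStudy(velocity=vel, magnitude=mag, spacing=spacing,
                     dt=float(meta["dt"]), venc=float(meta["venc"]), affine=affine)


# -- masks ----------------------------------------------------------------

def load_mask(path: str | Path, study: FlowStudy, label: str = "LA") -> ChamberMask:
    """Load a chamber mask (HDF5 ``/mask`` or a NIfTI volume) and verify it
    sits on the study grid.  Any nonzero voxel counts as inside."""
    fmt = _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "mask" not in f:
                raise ValidationError(f"{path}: missing dataset /mask")
            raw = f["mask"][...]
            label = str(f["mask"].attrs.get("label", label))
    else:
        raw = np.asarray(nib.load(str(path)).dataobj)
    mask = ChamberMask(mask=raw != 0, label=label)
    mask.check_against(study)
    return mask


def save_mask(mask: ChamberMask, path: str | Path, study: FlowStudy | None = None) -> None:
    fmt = _infer_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "a") as f:
            if "mask" in f:
                del f["mask"]
            f.create_dataset("mask", data=mask.mask.astype(np.uint8), track_times=False)
            f["mask"].attrs["label"] = mask.label
    else:
        affine = study.affine if study is not None else np.eye(4)
        nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))
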