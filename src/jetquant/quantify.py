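"""Jet flow-rate and momentum-rate quantification.

The two summation rules at the heart of the method, evaluated over the
contoured jet region Ω_jet on each through-plane map:

    Q_jet = Σ_i V⊥_i · dA                         (flow rate)
    M_jet = ρ · Σ_i sgn(V⊥_i) · V⊥_i² · dA        (axial momentum rate)

with V⊥ in cm/s, dA in mm² and ρ = 1.0 g/cm³ (blood approximated as
water); results are reported in mL/s and mN.  Per-plane series are
integrated over the regurgitant interval (rectangular rule, frame duration
Δt) to the regurgitant volume RVol_jet (mL) and time-integrated momentum
RMom_jet (mN·s).  The module also houses severity grading, the per-plane
percent-change profile, and the momentum-convergence criterion that selects
the optimal measurement plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QuantifyOptions
from .contour import JetContour, dual_velocity_contour
from .datamodel import ChamberMask, FlowStudy
from .planes import (MRInterval, ThroughPlaneMap, detect_mr_interval,
                     estimate_plane_normal, find_peak_velocity_voxel,
                     place_planes, reformat_throughplane)

RHO_BLOOD_G_CM3 = 1.0

# Severity thresholds in mL: MR1 <= 30 < MR2 <= 45 < MR3+
SEVERITY_MR1_MAX_ML = 30.0
SEVERITY_MR2_MAX_ML = 45.0
SEVERITY_GRADES = ("MR1", "MR2", "MR3plus")


@dataclass
class FlowTimeSeries:
    """Per-frame jet flow rate and momentum rate over the MR interval."""

    frames: np.ndarray          # frame indices t0..t_end
    q_ml_s: np.ndarray
    m_mn: np.ndarray
    dt_ms: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.q_ml_s = np.asarray(self.q_ml_s, dtype=float)
        self.m_mn = np.asarray(self.m_mn, dtype=float)
        if not (len(self.frames) == len(self.q_ml_s) == len(self.m_mn)):
            raise ValueError("series arrays must have equal length")


@dataclass
class PlaneProfile:
    """Per-plane integrated results indexed by axial offset x."""

    offsets_mm: np.ndarray
    rvol_ml: np.ndarray
    rmom_mns: np.ndarray
    series: dict[float, FlowTimeSeries]
    usable: np.ndarray
    interval: MRInterval
    log: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x_mm": self.offsets_mm, "rvol_ml": self.rvol_ml,
                             "rmom_mns": self.rmom_mns, "usable": self.usable})

    def rvol_at(self, x_mm: float) -> float:
        i = int(np.argmin(np.abs(self.offsets_mm - x_mm)))
        return float(self.rvol_ml[i])


@dataclass
class SeverityGrade:
    grade: str
    rvol_ml: float


class UndefinedProfileError(ValueError):
    """Reference-plane value is zero or missing; percent change undefined."""


# -- the two summation rules ----------------------------------------------

def jet_flow_rate(tpm: ThroughPlaneMap, contour: JetContour) -> float:
    """Q_jet in mL/s; signed V⊥, so opposed pixels cancel."""
    if not contour.pixels.any():
        return 0.0
    total = float(tpm.values[contour.pixels].sum())       # cm/s
    return total * tpm.pixel_area_mm2 * 0.01              # cm/s·mm² -> mL/s


def jet_momentum_rate(tpm: ThroughPlaneMap, contour: JetContour,
                      rho: float = RHO_BLOOD_G_CM3) -> float:
    """M_jet in mN, with the three-case sign convention sgn(V⊥)·V⊥²."""
    if not contour.pixels.any():
        return 0.0
    v = tpm.values[contour.pixels]
    total = float(np.sum(np.sign(v) * v ** 2))            # cm²/s²
    return rho * total * tpm.pixel_area_mm2 * 1e-4        # -> mN


def integrate_series(series: FlowTimeSeries) -> tuple[float, float]:
    """Rectangular-rule temporal integrals: (RVol in mL, RMom in mN·s)."""
    if len(series.frames) == 0:
        raise ValueError("cannot integrate an empty series")
    dt_s = series.dt_ms / 1000.0
    return (float(np.sum(series.q_ml_s) * dt_s),
            float(np.sum(series.m_mn) * dt_s))


# -- full-study quantification --------------------------------------------

def quantify_study(study: FlowStudy, mask: ChamberMask,
                   options: QuantifyOptions | None = None) -> PlaneProfile:
    """Run the complete per-frame pipeline: interval detection, peak
    tracking, plane fan placement, through-plane reformatting, dual-velocity
    contouring and the two summations, integrated per plane.

    When several jet seed points are configured, the full procedure runs
    once per jet and the per-plane RVol/RMom (and series) are summed, the
    rule used for double-jet regurgitation.
    """
    options = options or QuantifyOptions()
    mask.check_against(study)
    interval = detect_mr_interval(
        study, mask, speed_threshold_cm_s=options.interval.speed_threshold_cm_s,
        override=options.interval.override)

    seeds = options.tracking.seed_points_world_mm or [None]
    count = options.planes.count
    offsets = (np.arange(count) - count // 2) * options.planes.spacing_mm

    q_acc = np.zeros((count, len(interval.frames)))
    m_acc = np.zeros((count, len(interval.frames)))
    usable = np.ones(count, dtype=bool)
    log: list[dict] = [{"event": "interval", "t0": interval.t0,
                        "t_end": interval.t_end,
                        "override": options.interval.override is not None}]

    for seed in seeds:
        prev_peak = None
        for fi, t in enumerate(interval.frames):
            peak = find_peak_velocity_voxel(
                study, mask, t, prev_peak=prev_peak,
                seed_world_mm=None if seed is None else np.asarray(seed, float))
            prev_peak = peak
            center = study.world_from_voxel(np.asarray(peak, dtype=float))
            normal = estimate_plane_normal(study, peak, t)
            planes = place_planes(
                study, center, normal, t,
                spacing_mm=options.planes.spacing_mm, count=count,
                extent_mm=options.planes.extent_mm,
                pitch_mm=options.planes.pitch_mm)
            log.append({"event": "track", "frame": int(t), "seed": seed,
                        "peak_voxel": [int(v) for v in peak]})
            for pi, plane in enumerate(planes):
                if not plane.usable:
                    usable[pi] = False
                    log.append({"event": "unusable_plane", "frame": int(t),
                                "x_mm": plane.offset_mm})
                    continue
                tpm = reformat_throughplane(study, plane, t)
                cont = dual_velocity_contour(
                    tpm, inner_fraction=options.contour.inner_fraction,
                    outer_cm_s=options.contour.outer_threshold_cm_s)
                q_acc[pi, fi] += jet_flow_rate(tpm, cont)
                m_acc[pi, fi] += jet_momentum_rate(tpm, cont, rho=options.rho_g_cm3)
                if cont.empty_reason:
                    log.append({"event": "empty_contour", "frame": int(t),
                                "x_mm": plane.offset_mm,
                                "reason": cont.empty_reason})

    frames = np.array(list(interval.frames))
    series: dict[float, FlowTimeSeries] = {}
    rvol = np.full(count, np.nan)
    rmom = np.full(count, np.nan)
    for pi, x in enumerate(offsets):
        if not usable[pi]:
            continue
        s = FlowTimeSeries(frames=frames, q_ml_s=q_acc[pi], m_mn=m_acc[pi],
                           dt_ms=study.dt)
        series[float(x)] = s
        rvol[pi], rmom[pi] = integrate_series(s)

    return PlaneProfile(offsets_mm=offsets, rvol_ml=rvol, rmom_mns=rmom,
                        series=series, usable=usable, interval=interval,
                        log=log)


# -- grading and profile summaries ----------------------------------------

def classify_severity(rvol_ml: float) -> SeverityGrade:
    """Clinical grade from RVol: MR1 <= 30 mL < MR2 <= 45 mL < MR3+."""
    if rvol_ml < 0:
        raise ValueError(f"RVol must be non-negative, got {rvol_ml}")
    if rvol_ml <= SEVERITY_MR1_MAX_ML:
        grade = "MR1"
    elif rvol_ml <= SEVERITY_MR2_MAX_ML:
        grade = "MR2"
    else:
        grade = "MR3plus"
    return SeverityGrade(grade=grade, rvol_ml=float(rvol_ml))


def percent_change_profile(profile: PlaneProfile) -> pd.DataFrame:
    """Per-plane percent change of RVol and RMom relative to the reference
    plane at x = 0 (the tracked peak-velocity location)."""
    i0 = int(np.argmin(np.abs(profile.offsets_mm)))
    v0, m0 = profile.rvol_ml[i0], profile.rmom_mns[i0]
    if not np.isfinite(v0) or v0 == 0 or not np.isfinite(m0) or m0 == 0:
        raise UndefinedProfileError("reference plane (x = 0) value is zero or missing")
    return pd.DataFrame({
        "x_mm": profile.offsets_mm,
        "rvol_pct_change": 100.0 * (profile.rvol_ml - v0) / v0,
        "rmom_pct_change": 100.0 * (profile.rmom_mns - m0) / m0,
    })


def optimal_plane_by_momentum(profile: PlaneProfile, tol: float = 0.1
                              ) -> tuple[float, bool]:
    """Most upstream plane from which the momentum profile has converged.

    Returns ``(x_mm, converged)``: the smallest offset x such that RMom at
    all usable planes >= x lies within ±tol of their mean (at least two
    planes).  A free jet converges at the most upstream plane; with
    near-orifice signal loss the convergence point moves to (or beyond) the
    peak-velocity location.  A profile with no convergent tail is flagged
    and the plane of maximum RMom is returned instead.
    """
    ok = profile.usable & np.isfinite(profile.rmom_mns)
    xs = profile.offsets_mm[ok]
    ms = profile.rmom_mns[ok]
    if len(xs) < 3:
        raise ValueError("need at least three usable planes")
    order = np.argsort(xs)
    xs, ms = xs[order], ms[order]
    for start in range(len(xs) - 1):
        tail = ms[start:]
        mean = tail.mean()
        if mean > 0 and np.all(np.abs(tail - mean) <= tol * mean):
            return float(xs[start]), True
    return float(xs[np.argmax(ms)]), False
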