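"""Analytic pulsatile free-jet phantom with known ground truth.

The phantom emulates the flow physics a regurgitant mitral jet exposes to a
4D flow acquisition:

* **Momentum conservation.**  A free jet discharging into a large chamber
  conserves its axial momentum rate M(x, t) while it spreads.  Downstream of
  the orifice (jet axis coordinate ``x >= 0``) the axial velocity follows the
  self-similar round-jet profile ``u = Uc(x,t)·exp(-r²/b(x)²)`` with linear
  spreading ``b(x) = R + α(x + x0)`` and centerline decay
  ``Uc = √2·U0(t)·R/b(x)``, which makes
  ``M(x,t) = ρ·π·Uc²·b²/2 = ρ·π·R²·U0(t)²`` exactly independent of ``x``.
* **Entrainment.**  The volume flux ``Q(x,t) = π·Uc·b² = √2·π·R·b(x)·U0(t)``
  grows linearly with the half-width — the jet draws in surrounding fluid.
  The corresponding radial inflow follows from integral mass balance of the
  Gaussian profile and vanishes on the axis.
* **Upstream inflow column.**  Upstream of the orifice (``x < 0``, the
  confined tract feeding it) the profile is a momentum-conserving blunt
  column ``u = Up(x,t)·exp(-(r/b0)^p(x))`` with constant radius ``b0 = b(0)``
  and a bluntness exponent ``p(x) = 2 + κ·(−x)`` that rises away from the
  orifice.  Normalising the amplitude through the closed-form momentum of
  the generalised-Gaussian profile keeps ``M(x,t)`` exactly equal to the
  orifice value while the centerline velocity and the volume flux both drop
  upstream — so the global peak velocity sits at the orifice, where the
  quantification pipeline's tracked reference plane should land, and the
  volume flux is strictly increasing along the whole ±7.5 mm plane fan.
* **Near-orifice signal loss.**  Intravoxel phase dispersion at the orifice
  is modelled as multiplicative attenuation of the sampled velocity:
  ``1 − A·exp(−x/λ)`` downstream, saturating at ``1 − A`` in the upstream
  column, together with a colocated dip in the signal-magnitude volume.
* **Noise and aliasing.**  Optional additive Gaussian velocity noise and
  optional wrapping of components into ±VENC.

The waveform is a half-sine over systole.  Density is 1.0 g/cm³ (blood
approximated as water).  All closed forms used for ground truth are also
exposed as functions so tests can check them against numerical quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma as _gamma

from .datamodel import ChamberMask, FlowStudy

RHO_BLOOD_G_CM3 = 1.0


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration is geometrically inconsistent."""


@dataclass
class SignalLossConfig:
    enabled: bool = False
    depth_mm: float = 5.0          # λ: axial e-folding depth of the loss zone
    max_attenuation: float = 0.5   # A: fractional velocity loss at the orifice


@dataclass
class AliasingConfig:
    enabled: bool = False
    venc_cm_s: float = 250.0


@dataclass
class PhantomConfig:
    """Geometry, waveform and artefact settings of the synthetic jet.

    Defaults describe a severe-range regurgitant jet: 8 mm orifice,
    400 cm/s peak orifice velocity, 300 ms systole sampled at 30 ms,
    1 mm isotropic voxels (orifice diameter / 8).
    """

    orifice_diameter_mm: float = 8.0
    peak_orifice_velocity_cm_s: float = 400.0
    systole_duration_ms: float = 300.0
    n_frames: int = 12
    dt_ms: float = 30.0
    grid_shape: tuple[int, int, int] = (47, 47, 37)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orifice_axial_index: int = 12        # voxel k of the orifice plane (x = 0)
    orifice_center_mm: tuple[float, float] = (0.0, 0.0)  # transverse axis offset
    spreading_rate: float = 0.11         # α, half-width growth per unit length
    virtual_origin_offset_mm: float = 0.0
    upstream_bluntness_per_mm: float = 0.4   # κ in p(x) = 2 + κ·(−x)
    chamber_margin_voxels: int = 1
    signal_loss: SignalLossConfig = field(default_factory=SignalLossConfig)
    noise_sd_cm_s: float = 0.0
    aliasing: AliasingConfig = field(default_factory=AliasingConfig)
    seed: int = 0

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.orifice_diameter_mm

    @property
    def b0_mm(self) -> float:
        return self.radius_mm + self.spreading_rate * self.virtual_origin_offset_mm

    @property
    def orifice_area_cm2(self) -> float:
        """Orifice cross-sectional area π·(d/2)² in cm² — e.g. 0.79 cm² for a
        1 cm jet, the diameter needed for four-voxel coverage at 2.5 mm."""
        return float(np.pi * (self.radius_mm / 10.0) ** 2)

    def validate(self) -> None:
        for name in ("orifice_diameter_mm", "peak_orifice_velocity_cm_s",
                     "systole_duration_ms", "dt_ms", "spreading_rate"):
            if not getattr(self, name) > 0:
                raise PhantomConfigError(f"{name} must be positive")
        if not (0 <= self.signal_loss.max_attenuation < 1):
            raise PhantomConfigError("signal_loss.max_attenuation must lie in [0, 1)")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomConfigError("spacing_mm must be positive")
        if not (0 <= self.orifice_axial_index < self.grid_shape[2]):
            raise PhantomConfigError("orifice_axial_index outside the grid")


@dataclass
class PhantomTruth:
    """Analytic ground truth for parameter-recovery tests."""

    times_ms: np.ndarray          # frame times
    q0_ml_s: np.ndarray           # orifice-plane volume flux per frame
    m0_mn: np.ndarray             # axial momentum rate per frame (all x)
    rvol_ml: float                # Σ q0·Δt
    rmom_mns: float               # Σ m0·Δt
    axis_origin_mm: np.ndarray    # orifice center, world mm
    axis_direction: np.ndarray    # unit jet axis (world)
    config: PhantomConfig


# -- closed-form building blocks ------------------------------------------

def _waveform(t_ms: float | np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Half-sine systolic waveform, zero outside [0, systole]."""
    t = np.asarray(t_ms, dtype=float)
    w = np.sin(np.pi * t / cfg.systole_duration_ms)
    return np.where((t >= 0) & (t <= cfg.systole_duration_ms), np.maximum(w, 0.0), 0.0)


def _half_width_mm(x_mm: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Jet half-width b(x); constant at b0 in the upstream column."""
    x = np.asarray(x_mm, dtype=float)
    return np.where(x >= 0,
                    cfg.b0_mm + cfg.spreading_rate * np.maximum(x, 0.0),
                    cfg.b0_mm)


def _bluntness(x_mm: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Profile exponent p(x): 2 (Gaussian) downstream, rising upstream."""
    x = np.asarray(x_mm, dtype=float)
    return np.where(x >= 0, 2.0, 2.0 + cfg.upstream_bluntness_per_mm * (-x))


def _amplitude_factor(x_mm: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    """Centerline velocity / (U0·w): momentum-normalised at every station.

    For the profile exp(−(r/b)^p) the momentum rate is
    ``ρ·π·b²·Up²·2^(−2/p)·Γ(1+2/p)``; setting it equal to ``ρ·π·R²·U0²``
    gives ``Up = U0·(R/b)·2^(1/p)/√Γ(1+2/p)``, which reduces to the familiar
    ``√2·U0·R/b`` for the Gaussian p = 2.
    """
    x = np.asarray(x_mm, dtype=float)
    b = _half_width_mm(x, cfg)
    p = _bluntness(x, cfg)
    return (cfg.radius_mm / b) * 2.0 ** (1.0 / p) / np.sqrt(_gamma(1.0 + 2.0 / p))


def analytic_centerline_velocity(x_mm, t_ms, cfg: PhantomConfig) -> np.ndarray:
    """Axial centerline velocity at station x and time t, cm/s."""
    return (cfg.peak_orifice_velocity_cm_s * _waveform(t_ms, cfg)
            * _amplitude_factor(x_mm, cfg))


def analytic_flow_rate(x_mm, t_ms, cfg: PhantomConfig) -> np.ndarray:
    """Jet volume flux Q(x, t) in mL/s (closed form, no truncation).

    ``Q = π·b²·Up·Γ(1+2/p) = π·R·b·U0·w·2^(1/p)·√Γ(1+2/p)``; strictly
    increasing in x (entrainment downstream, profile filling-out upstream).
    """
    x = np.asarray(x_mm, dtype=float)
    b = _half_width_mm(x, cfg)
    p = _bluntness(x, cfg)
    g = 2.0 ** (1.0 / p) * np.sqrt(_gamma(1.0 + 2.0 / p))
    q_cm_s_mm2 = (np.pi * cfg.radius_mm * b * g
                  * cfg.peak_orifice_velocity_cm_s * _waveform(t_ms, cfg))
    return q_cm_s_mm2 * 0.01  # cm/s·mm² -> mL/s


def analytic_momentum_rate(t_ms, cfg: PhantomConfig, rho: float = RHO_BLOOD_G_CM3) -> np.ndarray:
    """Axial momentum rate M0(t) in mN — independent of x by construction."""
    u = cfg.peak_orifice_velocity_cm_s * _waveform(t_ms, cfg)
    m_raw = rho * np.pi * cfg.radius_mm ** 2 * u ** 2   # g/cm³·cm²/s²·mm²
    return m_raw * 1e-4  # -> mN


def _attenuation(x_mm: np.ndarray, cfg: PhantomConfig) -> np.ndarray:
    if not cfg.signal_loss.enabled:
        return np.ones_like(np.asarray(x_mm, dtype=float))
    a = cfg.signal_loss.max_attenuation
    lam = cfg.signal_loss.depth_mm
    x = np.asarray(x_mm, dtype=float)
    return np.where(x >= 0, 1.0 - a * np.exp(-x / lam), 1.0 - a)


def analytic_jet_velocity(position_mm: np.ndarray, t_ms: float,
                          cfg: PhantomConfig) -> np.ndarray:
    """Evaluate the analytic velocity vector field at world positions, cm/s.

    ``position_mm`` has shape (..., 3); the jet axis is the world +z axis
    through ``(orifice_center_mm, 0)``.  Points outside the chamber box or
    outside the jet envelope (r > 3b) return zero.
    """
    pos = np.asarray(position_mm, dtype=float)
    out = np.zeros(pos.shape)
    w = float(_waveform(t_ms, cfg))
    if w == 0.0:
        return out

    ox, oy = cfg.orifice_center_mm
    px = pos[..., 0] - ox
    py = pos[..., 1] - oy
    x = pos[..., 2]                      # axial coordinate (orifice at z = 0)
    r = np.hypot(px, py)

    cmin, cmax = chamber_bounds_mm(cfg)
    inside = np.all((pos >= cmin) & (pos <= cmax), axis=-1)

    b = _half_width_mm(x, cfg)
    p = _bluntness(x, cfg)
    envelope = inside & (r <= 3.0 * b)

    u0w = cfg.peak_orifice_velocity_cm_s * w
    amp = _amplitude_factor(x, cfg) * u0w
    axial = amp * np.exp(-np.power(np.where(envelope, r, 0.0) / b, p))
    axial = np.where(envelope, axial, 0.0)

    # Entrained radial inflow (Gaussian region only): from continuity,
    # u_r = −(α·C/2r)·[1 − (2η+1)e^(−η)], η = r²/b², C = Uc·b = √2·U0·w·R.
    c_const = np.sqrt(2.0) * u0w * cfg.radius_mm
    eta = (r / b) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ur = -(cfg.spreading_rate * c_const / (2.0 * r)) * (
            1.0 - (2.0 * eta + 1.0) * np.exp(-eta))
    ur = np.where((r > 1e-9) & envelope & (x >= 0), ur, 0.0)

    att = _attenuation(x, cfg)
    out[..., 0] = np.where(r > 1e-9, ur * px / np.maximum(r, 1e-9), 0.0) * att
    out[..., 1] = np.where(r > 1e-9, ur * py / np.maximum(r, 1e-9), 0.0) * att
    out[..., 2] = axial * att
    return out


# -- grid sampling --------------------------------------------------------

def _affine(cfg: PhantomConfig) -> np.ndarray:
    """Voxel->world affine: transverse grid center at world (0, 0), orifice
    plane at world z = 0.  The jet axis runs through ``orifice_center_mm``,
    which moves it within the grid (two-jet configurations)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = cfg.spacing_mm
    ci = (cfg.grid_shape[0] - 1) // 2
    cj = (cfg.grid_shape[1] - 1) // 2
    aff[:3, 3] = -np.array([ci * cfg.spacing_mm[0],
                            cj * cfg.spacing_mm[1],
                            cfg.orifice_axial_index * cfg.spacing_mm[2]])
    return aff


def chamber_bounds_mm(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """World-space min/max corners of the chamber box (grid minus wall margin)."""
    aff = _affine(cfg)
    m = cfg.chamber_margin_voxels
    lo = np.array([m, m, m], dtype=float)
    hi = np.array(cfg.grid_shape, dtype=float) - 1 - m
    corner_lo = lo * np.diag(aff)[:3] + aff[:3, 3]
    corner_hi = hi * np.diag(aff)[:3] + aff[:3, 3]
    return corner_lo, corner_hi


def generate_phantom(cfg: PhantomConfig) -> tuple[FlowStudy, ChamberMask, PhantomTruth]:
    """Sample the analytic jet onto the acquisition grid.

    Returns the study (with noise/attenuation/aliasing applied as
    configured), the chamber mask, and the analytic ground truth.  Output is
    deterministic for a fixed config, including the seed.
    """
    cfg.validate()
    aff = _affine(cfg)
    cmin, cmax = chamber_bounds_mm(cfg)

    # jet envelope must stay inside the chamber transversally
    b_top = _half_width_mm(np.array([cmax[2]]), cfg)[0]
    half_w = min(cmax[0] - cfg.orifice_center_mm[0],
                 cfg.orifice_center_mm[0] - cmin[0],
                 cmax[1] - cfg.orifice_center_mm[1],
                 cfg.orifice_center_mm[1] - cmin[1])
    if 3.0 * b_top > half_w:
        raise PhantomConfigError(
            f"jet envelope (3b = {3 * b_top:.1f} mm at the chamber top) exceeds "
            f"the transverse chamber half-width {half_w:.1f} mm")

    nx, ny, nz = cfg.grid_shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1) * np.array(cfg.spacing_mm) + aff[:3, 3]

    inside = np.all((world >= cmin) & (world <= cmax), axis=-1)

    times = np.arange(cfg.n_frames) * cfg.dt_ms
    velocity = np.zeros((nx, ny, nz, cfg.n_frames, 3))
    for k, t in enumerate(times):
        velocity[..., k, :] = analytic_jet_velocity(world, t, cfg)

    magnitude = np.repeat(inside[..., None].astype(float), cfg.n_frames, axis=-1)
    if cfg.signal_loss.enabled:
        # dephasing dip colocated with the attenuated jet core
        ox, oy = cfg.orifice_center_mm
        r = np.hypot(world[..., 0] - ox, world[..., 1] - oy)
        b = _half_width_mm(world[..., 2], cfg)
        dip = np.where(r <= b, _attenuation(world[..., 2], cfg), 1.0)
        magnitude *= dip[..., None]

    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sd_cm_s > 0:
        velocity = velocity + rng.normal(0.0, cfg.noise_sd_cm_s, size=velocity.shape)
    if cfg.aliasing.enabled:
        venc = cfg.aliasing.venc_cm_s
        velocity = np.mod(velocity + venc, 2 * venc) - venc
        venc_out = venc
    else:
        venc_out = max(250.0, 1.2 * np.abs(velocity).max())

    study = FlowStudy(velocity=velocity, magnitude=magnitude,
                      spacing=np.array(cfg.spacing_mm), dt=cfg.dt_ms,
                      venc=venc_out, affine=aff)
    mask = ChamberMask(mask=inside, label="LA")

    q0 = analytic_flow_rate(0.0, times, cfg)
    m0 = analytic_momentum_rate(times, cfg)
    truth = PhantomTruth(
        times_ms=times, q0_ml_s=q0, m0_mn=m0,
        rvol_ml=float(np.sum(q0) * cfg.dt_ms / 1000.0),
        rmom_mns=float(np.sum(m0) * cfg.dt_ms / 1000.0),
        axis_origin_mm=np.array([*cfg.orifice_center_mm, 0.0]),
        axis_direction=np.array([0.0, 0.0, 1.0]),
        config=replace(cfg),
    )
    return study, mask, truth
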