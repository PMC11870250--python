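"""Shared fixtures: phantom studies at the reference conditions.

The clean phantom (8 mm orifice, 400 cm/s peak, 1 mm voxels = d/8, no
noise, no signal loss) and its signal-loss counterpart are generated once
per session; quantification runs are cached alongside.
"""

from __future__ import annotations

import numpy as np
import pytest

from jetquant import PhantomConfig, generate_phantom, quantify_study
from jetquant.phantom import SignalLossConfig


@pytest.fixture(scope="session")
def clean_phantom():
    cfg = PhantomConfig()
    study, mask, truth = generate_phantom(cfg)
    return cfg, study, mask, truth


@pytest.fixture(scope="session")
def clean_profile(clean_phantom):
    _, study, mask, _ = clean_phantom
    return quantify_study(study, mask)


@pytest.fixture(scope="session")
def loss_phantom():
    cfg = PhantomConfig(signal_loss=SignalLossConfig(
        enabled=True, depth_mm=5.0, max_attenuation=0.5))
    study, mask, truth = generate_phantom(cfg)
    return cfg, study, mask, truth


@pytest.fixture(scope="session")
def loss_profile(loss_phantom):
    _, study, mask, _ = loss_phantom
    return quantify_study(study, mask)


@pytest.fixture()
def small_phantom():
    """A lighter jet for I/O and preprocessing tests."""
    cfg = PhantomConfig(orifice_diameter_mm=6.0, peak_orifice_velocity_cm_s=120.0,
                        grid_shape=(31, 31, 24), orifice_axial_index=8,
                        n_frames=8)
    study, mask, truth = generate_phantom(cfg)
    return cfg, study, mask, truth


def uniform_study(vector, shape=(8, 8, 8), n_frames=3, spacing=(1.0, 1.0, 1.0),
                  dt=30.0, venc=250.0):
    """A study with the same velocity vector everywhere."""
    from jetquant import FlowStudy

    vel = np.zeros((*shape, n_frames, 3))
    vel[...] = np.asarray(vector, dtype=float)
    mag = np.ones((*shape, n_frames))
    aff = np.diag([*spacing, 1.0])
    return FlowStudy(velocity=vel, magnitude=mag, spacing=np.array(spacing),
                     dt=dt, venc=venc, affine=aff)
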