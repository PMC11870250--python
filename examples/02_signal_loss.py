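"""Near-orifice signal loss and the momentum-convergence plane criterion.

Phase dispersion at the orifice underestimates velocities there, which
depresses both flow and momentum upstream and pushes the sampled peak
velocity downstream of the true orifice.  The momentum profile recovers and
flattens past the peak, so the most upstream plane where momentum has
converged — at the peak-velocity location — is the recommended place to
read off RVol.
"""

import numpy as np

from jetquant import PhantomConfig, generate_phantom, optimal_plane_by_momentum, quantify_study
from jetquant.phantom import SignalLossConfig

cfg = PhantomConfig(signal_loss=SignalLossConfig(enabled=True, depth_mm=5.0,
                                                 max_attenuation=0.5))
study, mask, truth = generate_phantom(cfg)
profile = quantify_study(study, mask)

peak_voxels = [e["peak_voxel"] for e in profile.log if e["event"] == "track"]
peak_world = study.world_from_voxel(np.asarray(peak_voxels[len(peak_voxels) // 2],
                                               dtype=float))
print(f"tracked peak-velocity point sits {peak_world[2]:.0f} mm downstream of "
      "the orifice (signal loss hides the true vena contracta)\n")

print(profile.to_dataframe().to_string(index=False,
                                       float_format=lambda v: f"{v:8.2f}"))

x = profile.offsets_mm
rvol, rmom = profile.rvol_ml, profile.rmom_mns
i0 = int(np.argmin(np.abs(x)))
print(f"\nupstream (x = -7.5 mm) RVol is {100 * (1 - rvol[0] / rvol[i0]):.0f}% "
      f"below the reference plane; RMom {100 * (1 - rmom[0] / rmom[i0]):.0f}% below")
tail = rmom[x >= 0]
print(f"downstream momentum drift: ±{100 * np.max(np.abs(tail - tail.mean())) / tail.mean():.1f}%")
x_opt, converged = optimal_plane_by_momentum(profile)
print(f"momentum-convergence plane: x = {x_opt:+.1f} mm (converged: {converged})")
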