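"""Generate the pulsatile jet phantom and quantify it plane by plane.

Builds an 8 mm-orifice, 400 cm/s regurgitant jet sampled on a 1 mm grid,
then runs the full tracked-plane pipeline: RVol_jet and RMom_jet at seven
planes 2.5 mm apart along the jet axis.  On a clean free jet the momentum
rate is the same at every plane (conservation) while the flow volume grows
downstream (entrainment) — so RVol is only trustworthy at the tracked
peak-velocity plane, which is where it matches the analytic ground truth.
"""

import numpy as np

from jetquant import (PhantomConfig, generate_phantom,
                      optimal_plane_by_momentum, percent_change_profile,
                      quantify_study)

cfg = PhantomConfig()
study, mask, truth = generate_phantom(cfg)
print(f"phantom: d = {cfg.orifice_diameter_mm} mm, "
      f"U0 = {cfg.peak_orifice_velocity_cm_s} cm/s, "
      f"grid {study.grid_shape} at {tuple(float(s) for s in study.spacing)} mm")
print(f"analytic truth: RVol = {truth.rvol_ml:.2f} mL, "
      f"RMom = {truth.rmom_mns:.2f} mN.s\n")

profile = quantify_study(study, mask)
table = profile.to_dataframe()
table["rvol_pct_vs_x0"] = percent_change_profile(profile)["rvol_pct_change"]
print(table.to_string(index=False, float_format=lambda v: f"{v:8.2f}"))

rvol0 = profile.rvol_at(0.0)
err = 100 * (rvol0 - truth.rvol_ml) / truth.rvol_ml
x_opt, converged = optimal_plane_by_momentum(profile)
print(f"\nRVol at the tracked peak-velocity plane: {rvol0:.2f} mL "
      f"({err:+.1f}% vs truth)")
rmom = profile.rmom_mns
print(f"RMom spread across planes: ±{100 * np.max(np.abs(rmom - rmom.mean())) / rmom.mean():.1f}% "
      "(free-jet momentum conservation)")
print(f"momentum-convergence plane: x = {x_opt:+.1f} mm (converged: {converged})")
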