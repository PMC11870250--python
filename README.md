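# jetquant

Direct quantification of valvular regurgitant jets from 4D flow
cardiovascular MR velocity fields.

## The problem

Mitral regurgitation severity is graded by the regurgitant volume (RVol) —
the blood leaked backward into the left atrium per heartbeat.  4D flow CMR
acquires three-directional velocities over a volume through the cardiac
cycle, so a measurement plane can be placed retrospectively *directly on
the regurgitant jet*.  But where along the jet?  Near the orifice,
intravoxel phase dispersion destroys signal and underestimates velocity;
further downstream, the jet entrains surrounding blood and its volume flux
grows beyond the true RVol.  The answer comes from free-jet fluid
dynamics: a jet discharging into a large chamber conserves its axial
momentum rate, so the momentum profile along the jet is flat except where
velocities are underestimated — and the most upstream plane at which the
momentum has converged (in practice, the peak-velocity location) is the
optimal place to read off RVol.

## The method

At each cardiac phase during regurgitation, the peak-velocity voxel inside
the receiving-chamber mask is tracked; a plane perpendicular to the jet
(normal = 3×3×3 median of the velocity vectors) is centered there, with
three further planes 2.5 mm apart on either side, each re-oriented to the
local flow.  Velocities are reformatted onto each plane's 0.5 mm pixel grid
(through-plane component V⊥, pixel area dA = 0.25 mm²), the jet region
Ω_jet is contoured by dual-velocity propagation (a core at 20% of the
plane-center velocity, dilated to the 0.1 m/s isovelocity boundary), and

    Q_jet(x) = Σ_{i∈Ω_jet} V⊥ᵢ · dA
    M_jet(x) = ρ · Σ_{i∈Ω_jet} sgn(V⊥ᵢ) · V⊥ᵢ² · dA ,   ρ = 1.0 g/cm³

are integrated over the regurgitant interval to RVol_jet (mL) and
RMom_jet (mN·s) per plane x ∈ {−7.5, …, +7.5} mm.  Severity grading uses
RVol ≤ 30 mL (MR 1), 30 < RVol ≤ 45 mL (MR 2), RVol > 45 mL (MR 3+).

Because no public 4D flow data ships with the package, an analytic
pulsatile free-jet phantom provides ground truth: a momentum-conserving
self-similar Gaussian jet with linear spreading (entrainment), a
momentum-conserving blunt inflow column upstream of the orifice, optional
near-orifice signal loss, velocity noise, and aliasing.  See
`docs/methods.md` for the model and its assumptions.

## Worked example

`python examples/01_phantom_quantify.py` generates the default phantom
(8 mm orifice, 400 cm/s peak orifice velocity, 1 mm voxels, 300 ms
half-sine systole at 30 ms frames) and quantifies it:

```
phantom: d = 8.0 mm, U0 = 400.0 cm/s, grid (47, 47, 37) at (1.0, 1.0, 1.0) mm
analytic truth: RVol = 53.86 mL, RMom = 120.64 mN.s

    x_mm  rvol_ml  rmom_mns  usable  rvol_pct_vs_x0
   -7.50    40.92    117.31    True          -22.06
   -5.00    42.30    117.73    True          -19.44
   -2.50    45.06    118.14    True          -14.20
    0.00    52.51    118.72    True            0.00
    2.50    56.00    118.92    True            6.64
    5.00    59.48    119.11    True           13.27
    7.50    62.95    119.24    True           19.88

RVol at the tracked peak-velocity plane: 52.51 mL (-2.5% vs truth)
RMom spread across planes: ±1.0% (free-jet momentum conservation)
momentum-convergence plane: x = -7.5 mm (converged: True)
```

Reading the numbers: RMom is flat across all seven planes (the free-jet
invariant holds on the clean phantom to ±1%), while RVol grows ~20% from
the reference plane to x = +7.5 mm — pure entrainment, not regurgitation —
and only the tracked peak-velocity plane recovers the true RVol (−2.5%).
`examples/02_signal_loss.py` adds near-orifice signal loss: the tracked
peak moves ~8 mm downstream of the orifice, upstream RVol/RMom collapse by
50%/63%, and the momentum-convergence criterion now selects x = 0 (the
peak-velocity plane) instead of the most upstream plane.
`examples/03_agreement_stats.py` runs the cohort statistics
(reclassification across planes, Bland-Altman, ICC(2,1), √3 uncertainty
inflation of subtraction-based volumetry).

## Command line

```sh
jetquant phantom  --config cfg.yaml --out study.h5      # + truth sidecar
jetquant quantify --study study.h5 --out results/       # results.h5 + summary.json
jetquant stats    --results-dir runs/ --out summary.json
jetquant all      --config cfg.yaml --out results/
```

Runs are fully described by a YAML config (unknown keys are rejected) and
are byte-for-byte reproducible for a fixed config and seed.

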