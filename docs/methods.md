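# Methods

## Quantification pipeline

The pipeline mirrors the semi-automatic direct-quantification workflow for
regurgitant jets in 4D flow CMR, replacing its manual steps with logged
automated surrogates:

1. **Regurgitant interval.**  The longest contiguous run of frames whose
   peak in-chamber speed exceeds a threshold (default 100 cm/s) is taken as
   t₀…t_end; a config override stands in for visual selection.
2. **Peak tracking.**  Per frame, the in-mask voxel of maximal speed.  Ties
   break toward the previous frame's peak (first frame: smallest linear
   index).  An optional seed point confines the search to the 26-connected
   high-speed region (≥ 20% of the frame maximum) containing it — the
   automated analogue of manually confirming the voxel lies in the jet of
   interest, and the mechanism for multi-jet studies.
3. **Plane orientation.**  The plane normal is the component-wise median of
   the ≤ 27 velocity vectors in the 3×3×3 neighbourhood (clipped at grid
   edges), normalised, sign-aligned with the center voxel's velocity.  A
   true geometric vector median is deliberately not used; the component-wise
   filter is the standard imaging reading and rejects single outliers.
4. **Plane fan.**  Seven planes at x ∈ {−7.5, …, +7.5} mm along the central
   normal (spacing 2.5 mm).  Off-center planes are re-oriented by the same
   median rule at their own centers, with two safeguards: the re-estimated
   normal is flipped, if needed, to face along the central normal (all
   planes follow one jet axis), and re-orientation falls back to the
   central normal where the local median flow is weaker than 10 cm/s —
   below that, the direction is noise (e.g. a plane center just outside
   the jet).  Planes whose center leaves the grid are flagged unusable,
   never silently dropped or zeroed.
5. **Reformat.**  Trilinear interpolation of the three velocity components
   on the plane's 0.5 mm pixel grid, projected on the normal
   (dA = 0.25 mm²).  The plane window is 40×40 mm (half-width 20 mm) —
   larger than three jet half-widths at x = +7.5 mm for any orifice
   ≤ 10 mm.  Out-of-volume pixels contribute zero and are flagged.
6. **Contour.**  Dual-velocity propagation: a 4-connected core at
   max(20% of |V_center|, 10 cm/s), then repeated single-pixel dilation
   (3×3 structuring element) admitting only same-signed pixels with
   |V⊥| ≥ 10 cm/s, until nothing more is admissible; the result is reduced
   to the 4-connected component containing the center.  Growth never
   crosses a sign change, so automatic contours cannot leak into
   counter-directional atrial inflow; manual edits may introduce mixed
   signs, which the summation rules handle through sgn(V⊥).
7. **Summation and integration.**  Q = Σ V⊥·dA (mL/s) and
   M = ρ·Σ sgn(V⊥)·V⊥²·dA (mN) with ρ = 1.0 g/cm³, integrated over
   t₀…t_end by the rectangular rule with the frame duration Δt — the
   natural reading of discrete acquisition — giving RVol (mL) and
   RMom (mN·s) per plane.  Multi-jet studies run the full procedure per
   seed point and sum per-plane results.

**Optimal plane.**  The momentum-convergence criterion returns the smallest
x whose trailing planes (≥ 2) all lie within ±10% of their mean RMom.  On a
clean free jet this is the most upstream plane; with near-orifice signal
loss it moves to the peak-velocity location.  A profile with no convergent
tail is flagged non-converging and the plane of maximum RMom is returned.
The 10% tolerance is a single-study stand-in for the cohort-level
"statistically unchanged" notion, which has no per-study analogue.

**Severity.**  RVol ≤ 30 mL → MR 1, 30 < RVol ≤ 45 mL → MR 2, > 45 mL →
MR 3+ (boundaries inclusive on the lower grade).

## Phantom model

The phantom is an analytic, axisymmetric, pulsatile free jet entering a
box-shaped chamber, sampled at voxel centers per frame.  It exists to give
the pipeline inputs with exactly known RVol/RMom and the three flow
features the method's error structure depends on.

* **Downstream (x ≥ 0): self-similar Gaussian round jet.**
  u(r, x, t) = U_c(x, t)·exp(−r²/b(x)²) with half-width
  b(x) = d/2 + α(x + x₀) (spreading rate α = 0.11, the classical value for
  turbulent round jets; virtual origin x₀ = 0 by default) and centerline
  U_c = √2·U0(t)·(d/2)/b(x).  This makes the axial momentum rate
  M = ρπU_c²b²/2 = ρπ(d/2)²U0(t)² exactly independent of x, while the
  volume flux Q = πU_c b² = √2·π·(d/2)·b(x)·U0(t) grows linearly with
  b — entrainment.  The radial inflow follows from integral mass balance,
  u_r = −(αC/2r)[1 − (2η+1)e^(−η)], η = r²/b², C = √2·U0(t)·d/2; it
  vanishes on the axis and is perpendicular to the measurement planes, so
  it never enters the through-plane sums.
* **Upstream (x < 0): momentum-conserving blunt inflow column.**  A pure
  self-similar Gaussian cannot extend upstream of the tracked peak: with
  momentum conserved, its centerline U_c ∝ 1/b is largest at the most
  upstream station, so the peak-velocity voxel — and with it the plane
  fan — would always sit at the upstream end of the field, leaving no
  usable upstream planes.  Physically, the flow feeding the orifice is a
  confined nozzle column with a blunt profile.  The phantom models it as
  u = U_p(x, t)·exp(−(r/b₀)^p(x)) with constant radius b₀ = b(0) and a
  bluntness exponent p(x) = 2 + κ·(−x) (κ = 0.4/mm) rising away from the
  orifice.  The generalised-Gaussian momentum integral has the closed form
  ρπb²U_p²·2^(−2/p)·Γ(1+2/p), so normalising
  U_p = U0·(d/2)/b₀·2^(1/p)/√Γ(1+2/p) keeps M(x, t) *exactly* equal to the
  orifice value at every station, while both the centerline velocity and
  the volume flux Q = π·(d/2)·b₀·U0·2^(1/p)·√Γ(1+2/p) decrease upstream.
  The global peak velocity therefore sits at the orifice, Q(x) is strictly
  increasing across the whole ±7.5 mm fan, and momentum is conserved
  everywhere — verified against radial quadrature to < 0.1%.  No radial
  component is modelled upstream (a confined column has nothing to
  entrain).
* **Waveform.**  Half-sine over a 300 ms systole, sampled at 30 ms frames
  (12 frames).  Defaults — 8 mm orifice, 400 cm/s peak orifice velocity,
  1 mm isotropic voxels (= d/8), 47×47×37 grid — describe a severe-range
  regurgitant jet (true RVol ≈ 54 mL) resolved well enough that
  discretisation, not resolution, dominates the measurement error; the
  whole pipeline runs in seconds at this size.
* **Signal loss.**  Multiplicative velocity attenuation
  1 − A·exp(−x/λ) for x ≥ 0, saturating at 1 − A through the upstream
  column (defaults A = 0.5, λ = 5 mm when enabled), plus a colocated dip in
  the magnitude volume.  This reproduces the observed pattern — upstream
  flow and momentum depressed, the sampled peak displaced a few mm
  downstream of the orifice, momentum recovering and flattening past the
  peak — as an effect-level model; it is not a Bloch-level dephasing
  simulation.
* **Noise and aliasing.**  Additive Gaussian velocity noise (seeded) and
  optional wrapping of components into ±VENC.

What the phantom does *not* emulate: eccentric wall-attached jets (no
momentum loss to wall friction, no restricted entrainment), turbulent
fluctuations, valve motion, chamber inflow patterns, and realistic coil
magnitude images.  Passing tests therefore demonstrate correctness of the
geometry, contouring, summation and integration machinery under the
free-jet assumptions — not robustness to eccentric in-vivo jets, which is
a known limitation of the momentum argument itself.

## Preprocessing

* **Background phase offset.**  Static tissue = voxels with temporal speed
  SD and mean speed both < 5 cm/s.  A 2nd-order 3D polynomial (10
  coefficients, world-mm basis) is least-squares fitted per velocity
  component to the time-averaged velocity over static voxels and subtracted
  from all frames.  Fewer than 30 static voxels → no fit, warning flag.
  Slow coherent flow (e.g. entrained inflow) that sneaks under the static
  threshold biases the fit by a fraction of a cm/s; the jet itself, orders
  of magnitude faster, is untouched (< 1% peak change).
* **Aliasing.**  Temporal unwrapping with period 2·VENC (components jumping
  by more than VENC between frames are shifted by multiples of 2·VENC),
  followed by recentering of any series the unwrap drove beyond 2.5·VENC.
  A wrap constant over the whole series produces no temporal jump and is
  left unchanged — a documented limitation of any temporal-only method.
  Both corrections are idempotent.

## Statistics

Bland-Altman bias and 1.96·SD limits of agreement; ICC(2,1) (two-way
random effects, single measure, absolute agreement — the standard variant
for inter-method and inter-observer agreement of continuous measures),
computed through pingouin and cross-checked in the tests against the
mean-squares decomposition; root-sum-square propagation of independent
uncertainties (three ±10 mL volumes combine to ±17.3 mL — the case against
subtraction-based indirect volumetry); severity reclassification tables
across planes; and the non-trivial-regurgitation filter
(RVol ≥ 10 mL at x = 0).  Paired t/Wilcoxon helpers are provided as thin
textbook utilities.

## Numerical choices and degenerate inputs

* Internal units: cm/s, mm, ms; flow mL/s, momentum rate mN, RVol mL,
  RMom mN·s.  Converters only at I/O boundaries.  All plane geometry in
  world mm via the affine — voxel grids may be anisotropic.
* HDF5 is the lossless native container (float32, no timestamps, so equal
  runs give equal bytes); NIfTI (quadruplet or 5D + magnitude) for
  interoperability, with venc/dt/units in the header description.
* Trilinear reformat is exact for fields affine in position (tested for
  arbitrary oblique planes); interpolation clamps at grid edges.
* Empty contour (plane-center |V⊥| < 10 cm/s) → Q = M = 0 with a logged
  reason.  Zero-length median normals raise; off-center planes fall back
  to the central normal.  A study with no frame above the jet threshold
  raises a no-jet error rather than returning zeros.
* Determinism: a fixed config + seed reproduces results files
  byte-for-byte, including phantom noise.
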