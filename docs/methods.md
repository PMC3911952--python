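# Methods

This note documents the models implemented in `ureteroflow`, their
assumptions, the parameters that matter, and the numerical choices made
where the design was genuinely open.

## Geometry and obstruction severity

The ureter lumen is a body of revolution described by inner diameters
`D_i` at 16 equally spaced stations (i = 0 at the ureteropelvic junction,
i = 15 at the vesicoureteric junction), total length `L`. Between
stations the diameter interpolates piecewise-linearly; this is the
natural reconstruction for a conduit measured as a series of discrete
rings. All interfaces use mm and mm²; physics is computed in SI with the
conversions fixed in `units.py` (1 cmH₂O = 98.0665 Pa,
1 ml/min = 1.6667·10⁻⁸ m³/s, 1 cP = 10⁻³ Pa·s).

Severity of a sphere-with-hole occlusion is the affine area ratio

    OB% = 100 * (1 - A_gap / A_sphere),   A_gap = A_PShole - A_s.

This is the unique affine form satisfying the two anchor conditions the
construction demands: OB% = 100 exactly when the stent fills the hole
(A_gap = 0), and reduction to the distributed form
`OB_i% = 100 * A_s / A_i` when the hole is the local lumen itself
(A_PShole = A_sphere = A_i). Attainable severities for a given
sphere/stent pairing lie in [100·A_s/A_sphere, 100] — about
[11.7, 100] for the default 6.07 mm sphere and 2.08 mm stent — and
`hole_area_for_severity` inverts the formula exactly on that interval.

## Lumped hydraulic network

Assumptions: rigid walls (no distension, no peristalsis), steady fully
developed laminar flow in every branch, Newtonian fluid, bladder as an
open end at zero gauge pressure, renal pelvis as a zero-resistance
chamber (its 2 cm bore dwarfs the conduit). Under these assumptions
every branch is a linear resistor and the network solve is a sparse
symmetric-positive-definite nodal analysis; pelvic pressure is exactly
linear in inflow and viscosity.

Branch closures:

* stent lumen and bare-conduit segments: Hagen–Poiseuille
  `R = 128 μ L / (π D⁴)`; conduit segments between stations use the
  closed-form integral for a linear taper;
* extra-luminal space: concentric-annulus solution
  `R = 8 μ L / π · [Ro⁴ − Ri⁴ − (Ro² − Ri²)²/ln(Ro/Ri)]⁻¹`, integrated
  piecewise along the axially varying bore (8 sub-intervals per segment);
  the annulus is assumed coaxial;
* side holes: short pipes of length equal to the stent wall thickness
  (0.4 mm);
* the partially open gap at the sphere: a short annulus of length equal
  to the sphere diameter whose flow area is A_gap — the lowest-order
  laminar closure for a drilled passage. At OB% = 100 the branch is
  omitted entirely, so no extra-luminal path crosses the obstruction.

Side-hole layout is not part of the published geometry; the default is
one hole every 10 mm with the first hole placed so that holes 5 and 6
straddle the obstruction plane in the upper ureter, matching where the
sphere lodges relative to the hole numbering. Holes at negative axial
coordinate lie on the pelvic curl and open directly into the pelvis
node. Both spacing and offset are configurable. The surplus stent
length beyond the conduit (41 cm vs ~29 cm) is split evenly between the
two curls, and the whole lumen length is resistive.

Known limitation: entrance/exit (minor) losses and fitting compliance
are neglected — Reynolds numbers are small at ≤ 20 ml/min, but this is
the main expected source of deviation from bench-measured resistances at
low obstruction levels, where measured slopes also carry nonzero
intercepts. The model is therefore validated against the
fully-obstructed, lumen-confined configuration (where the analytic
Poiseuille value ≈ 1.057 cmH₂O/(ml/min) applies) and against monotone
trends (pressure non-decreasing in Q, μ and OB%), not against every
measured table cell.

Pressure classification: safe below 15 cmH₂O, dangerous above
20 cmH₂O; both boundary values are assigned to the warning band, a
convention needed because the published bands use strict inequalities on
both sides.

## Side-hole CFD

Domain: the extra-luminal gap just downstream of a complete occlusion,
a 10.8 × 1.5 mm rectangle with x = 0 at the occlusion wall and y = 0 at
the stent outer wall. The 0.8 mm hole spans x ∈ [5.0, 5.8] mm on the
stent wall: the 5 mm occlusion-to-hole distance is read as distance to
the hole *leading edge*; the alternative reading (to the hole centre)
shifts the geometry by 0.4 mm and is exposed as `distance_to="center"`.
Boundary conditions: no-slip on the occlusion, stent and ureter walls;
uniform normal velocity v_h across the hole (only the mean exit velocity
is known, so no profile shape is assumed); zero-streamwise-gradient
outflow with a global mass correction on the right.

Discretisation: uniform square staggered grid (pressure at cell
centres, velocities on faces), central differencing for diffusion and
hybrid central/upwind convection switched on the cell Peclet number.
SIMPLE iteration: implicit under-relaxed momentum predictor
(α_u = 0.7), pressure-correction Poisson solve, pressure update with
α_p = 0.3, iterated until all scaled residuals (momentum and
continuity) fall below 10⁻⁶. The five-point systems are solved directly
(sparse LU); factorisations are reused across iterations with
defect-correction sweeps against the current matrix, which leaves the
converged solution unchanged while cutting runtime several-fold. The
pressure-correction level is pinned at one reference cell. A Reynolds
cap (default 500 on the hole Reynolds number ρ·v_h·d/μ) refuses
configurations outside the steady-laminar regime.

Default production spacing is 0.025 mm (432 × 60 cells), chosen so a
solve completes in well under a minute on one core; the grid-convergence
check shows centreline speeds move by < 1% between 0.05 and 0.025 mm at
v_h = 0.01 m/s. Finer spacings (e.g. 0.01 mm) are available through the
same API. Validation anchors: plane-Poiseuille channel flow reproduces
the parabolic closed form to < 0.1% at these spacings, and the global
mass defect at convergence is at machine precision by construction of
the outflow correction.

Eddy characterisation: the streamfunction is integrated from the face
velocities (exact for a discretely divergence-free field); an eddy is an
interior strict local extremum of ψ whose same-sign region does not
discharge significant streamfunction through an open boundary — i.e. its
recirculation closes inside the domain. A streamfunction maximum is a
counter-clockwise eddy. Each eddy carries its centre, sense, peak speed
within its region and ψ value; `match_eddies` pairs eddies across runs
by sense and nearest centre, and `centerline_minima` provides the
independent location estimate (speed minima along y = gap/2), which
agrees with the ψ extrema to within a few cells. Pathlines are
integrated with RK4 on bilinearly interpolated velocities using a
speed-adaptive step (CFL 0.25 of a cell per step).

## Synthetic data

The generator produces the inputs the pipeline needs, under the study's
conditions; defaults are not tuning knobs:

* **Profile**: deterministic taper wide-to-narrow with its single
  interior minimum pinned at station 12 to 2.2 mm, proximal diameter
  6.8 mm (so a 6.07 mm sphere lodges between stations 0 and 1), plus
  station-wise Gaussian jitter of sd 0.05 mm (other stations floored
  above the minimum so its location is invariant); length drawn from
  Normal(289, 20) mm. Only the printed anchors (length, minimum
  diameter and its station) are enforced; the rest of the shape is a
  plausible reconstruction, not data.
* **Recordings**: model prediction plus homoscedastic Gaussian noise on
  pressure, truncated at zero, N = 3 replicates, over the full
  experimental grid (Q ∈ {5, 10, 15, 20} ml/min,
  μ ∈ {1, 1.3, 1.7, 2.5, 3.7, 6} cP, obstruction levels from bare
  conduit to OB% = 100). The default noise sd of 0.1 cmH₂O is scaled to
  error-bar magnitude and is a stand-in: the real replicate variance is
  not published. Because the generator is the lumped model itself,
  recovery tests demonstrate the statistical pipeline, not the model's
  fidelity to a real ureter.
* **Vortex fields**: superposed Gaussian-streamfunction vortices,
  divergence-free by construction with known extrema — ground truth for
  the eddy detector.

All randomness derives from one integer seed; outputs are byte-stable
under a fixed seed.

## Statistics

Pressure-flow fits are ordinary least squares with intercept
(`scipy.stats.linregress` behind the module surface), R² defined about
the mean. Replicates are averaged per flow rate before fitting, matching
how mean ± error-bar data are reduced; with balanced replicates the raw
fit gives the identical slope and both paths are available. Negative
fitted slopes are reported as-is. The Monte-Carlo calibration check
(σ = 0.5 cmH₂O, N = 3, 200 seeds) compares recovered slopes against
±3 standard errors computed from the *known* generator noise,
SE = (σ/√N)/√Sxx: with only four flow rates, the residual-estimated SE
has 2 degrees of freedom and a ±3·SE interval covers barely 90%, so the
known-σ form is the statistically meaningful criterion (normal coverage
99.7%).

## Problem sizes used in the shipped checks

Unit tests run the CFD at 0.1–0.15 mm spacing; the acceptance tests run
the production 0.025 mm grid for the channel benchmark, mass defect,
dead-end eddy existence and grid convergence, and compare eddy strengths
between v_h = 0.01 and 0.1 m/s at 0.05 mm, where the two resolutions
agree to within the stated convergence band.
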