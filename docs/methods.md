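# Methods

`fanfold` models one section of the radially pleated anal fan of a
dermapteran (earwig) hindwing as a bar-and-hinge multibody system with
tension-only elastic tendons, and asks under which combinations of tendon
stiffness, resting length and actuating torque the section folds and
unfolds between its two stable states.

## Crease-pattern construction

The geometry is generated from four parameters: proximal and distal
segment lengths `l_proximal`, `l_distal` (default 25 cm each — the
upscaled engineering geometry), the fan-centre radius `r` (5 cm) and the
angular segment width `theta` (15°), with `n` repeating fan units.  The
folded configuration is drawn first: the centre `O`, the tip point `A` at
`l_proximal + l_distal` on the axis, the transversal ring-fold line `M–N`
at the proximal length, and anchors `H_0 … H_{n+2}` spaced `theta` apart
on the centre circle.  The radial lines `H_i–A` cross `M–N` at the points
`F_i` under the deflection angles `phi_i` (reported as the acute angle
between the radial line and `M–N`).  Unfolding mirrors each unit across
its base chord `H_{i-1}–H_i`, inserts the intercalary fold lines by a
`theta` rotation about `H_i`, and deflects every distal sub-segment by
mirroring the proximal direction across the local ring-fold line — a
deviation of exactly `180° − 2 phi_i` from straight.  All steps are planar
isometries, so segment lengths are preserved to machine precision and the
pattern folds back exactly.  `2n+3` radial lines are computed so that the
deflections of the last unit are well defined; the final two are flagged
auxiliary and only `2n+1` enter the model.  Flat-foldability of the
simplified construction requires `n·theta ≤ 90°`.

## Bar-and-hinge model

Each retained radial fold line becomes a strut of two rigid cylindrical
bars (diameter 0.1 cm, density 1.25×10⁻³ kg/cm³; cylinder mass and
inertia in closed form).  Per strut:

* a proximal joint at the base anchor.  Its actuated `rx` axis is the fan
  axis (`O→A` direction), so alternating torque pleats neighbouring struts
  in opposite directions — the radial fold.  The pleat range is limited to
  ±90°, where neighbouring pleats stack; `ry`/`rz` are carried in the
  model description but locked by default (no force element acts on them).
* a distal hinge at the ring-fold crossing, axis along the local ring-fold
  line, limited to fold to 180° and to overbend by 3° in the open state,
  with the range flipped in sign for every second strut (the
  mountain/valley alternation).
* one tension-only spring-damper tendon spanning the distal joint,
  attached at a configurable fraction (default 0.2) of each bar's length
  from the joint.  For the standard geometry this puts the flat-state
  length at ≈ 11 cm.  The force is `k (l − l_r) + c l̇` when `l > l_r`,
  clamped to pure tension, and identically zero at or below the resting
  length (resilin-like free contraction).  Damping is constant,
  `c = 0.01 N per cm/s`.

Two zero-stiffness guide tendons per unit run parallel to the ring fold on
its distal side between neighbouring struts.  They exert no force by
default (an optional length limit is available but off); in this backend
the flat-state lock emerges per strut instead (below).

The membrane is treated as massless and purely visual; contact forces are
not modelled, so the wing may self-penetrate — the known source of
residual folded-state tendon elongation (`U_b ≠ 0`) at short resting
lengths.  Gravity is off by default and configurable.

## Dynamics

The equations of motion of each two-hinge strut chain are evaluated
exactly: mass matrices from body Jacobians of the cylinder inertias, and
velocity-product terms from a Newton–Euler pass with zero joint
acceleration.  Integration is semi-implicit Euler — velocity first, then
position — at `h = 0.005 s`.  Joint limits are compliant (torsional
spring-dampers beyond the range, default 3000 N·cm/rad), so fold angles
transiently exceed ±180° and oscillate, as with a compliant-constraint
engine.  For stability at the working timestep, constraint damping and the
linearised spring gradients (including the tendon's transverse `F/l` term,
which dominates near the fold where the attachment points nearly
coincide) are folded into the velocity update implicitly; applied torques,
spring forces and the small hinge damping (0.01 N·cm·s/rad, the
convergence counterpart of the tendon damper where the tendon is slack)
remain explicit.  The fold-side stop of the distal hinges is strongly
damped (an arriving flap settles onto the stack) while the pleat stop is
lightly damped and bounces; that rattling is what re-kicks not-yet-folded
joints.  Everything is vectorised over a batch of model instances
differing in `(k, l_r, torque)`, so a whole sweep column advances in one
run; results are independent of batch order.  Divergence (non-finite state
or |velocity| > 10⁶ rad/s) freezes the instance and flags it — a sweep
cell diagnostic, never an abort.

Units: the simulation state is advanced on raw numbers in a cm/kg/N/s
system — stiffness in N/cm, torque in N·cm, lengths in cm — and energies
are converted to Joules by the explicit 10⁻² (N·cm → N·m) factor in the
energy formulas.  The printed energy values are therefore exact unit
conversions of the raw simulation numbers.

## States, actuation and energies

Folding applies constant torque `M_alpha` on the proximal `rx` joints
only, in alternating directions; the ring fold is passive.  The fold
sequence in this backend: the pleat transient kicks the distal joints over
the small tendon barrier at `delta = 0` (the barrier height,
`~k (l_i − l_r) Δl`, is of order 10⁻³–10⁻² J), after which the tendons
release their stored energy into the ring fold — radial fold first, ring
fold second.  Unfolding applies `M_delta` directly on the distal hinges
plus `M_alpha` proximally, both alternating.

Three canonical states are detected on trajectories: `a` (flat/open — all
sign-adjusted fold angles inside the 0–3° overbend band, low kinetic
energy), `b` (folded — all fold depths ≥ 175°, sustained for 1 s) and `c`
(re-opened after an unfold schedule).  The band tolerance (3°), the 175°
fold band and the 1 s dwell are detection configuration, chosen to be
robust to the limit-compliance overshoot and oscillation; folding time is
reported from torque onset to the `b` detection.  The flat state locks:
the taut tendon presses every fold angle into its overbend stop, and
perturbations of ≤ 1° decay back.

Tendon energy is `U_t = 10⁻² · ½ k (l_t − l_r)²`, zero when slack.  Input
energies use the net angular displacements between state snapshots (for
constant torques this equals the work done):
`E_ab = 10⁻² Σ (−1)^{i+1} M_alpha Δalpha_i` and
`E_bc = 10⁻² Σ [(−1)^i M_alpha Δalpha_i + (−1)^{i+1} M_delta Δdelta_i]`,
angles in radians.  Energy reports carry the snapshot times `t_a/t_b/t_c`
because the values are sensitive to the exact timestep chosen.

## Parameter sweeps

The study grid: `k` = 10–60 N/cm (step 10), `l_r` = 0–9 cm (step 1), fold
torques 0–50 N·cm (step 10), unfold torques up to 100 N·cm (step 10) on
both joint families, timestep scan `h` = 0.0030–0.0050 s (step 0.0005).
Fold runs last 300 s of simulated time, unfold runs 100 s.  For each cell
torques are tried in ascending order and the minimum successful torque,
its folding time and the energy bookkeeping are recorded.

Unfolding is analysed independently of the folding history: each cell is
placed in the folded stack analytically and settled to equilibrium before
the unfold torque is applied.  (A 500 N·cm accelerated-fold schedule is
available, but in this backend so violent a pleat destabilises several
cells, so the constructed folded start is the default protocol.)  Every
run starts from a numerically settled state: a short strongly-damped
unactuated segment finds the cambered locked equilibrium before actuation.

## What the synthetic tensile generator emulates

The material module analyses cyclic tensile tests of printed elastomer
tendons: engineering strain/stress from the specimen dimensions
(`l0 = 60 mm`, `A0 = 6 mm²` — the test specimen; the printed tendon's
5 mm² cross-section is a separate field), a pointwise secant modulus
`E = σ/ε` with the first cycle excluded (Mullins softening), binned by
10% strain increments.  The synthetic generator reproduces the features
such tests show — loading/unloading hysteresis with non-negative loop
area, first-cycle stiffening, a zero-force plateau on unloading below 35%
strain, strain-dependent secant modulus bounded near 40 MPa for the
TPU-like defaults, multiplicative measurement noise — and is deterministic
per seed.  It does not emulate cycle-to-cycle creep drift or rate
dependence, so passing recovery tests demonstrate the analysis pipeline,
not a constitutive model.  Tendon sizing uses the proportionality of axial
stiffness to cross-sectional area at fixed length and modulus.

## Design choices and limitations

This backend realises the model's ingredients (strut chains,
limit-flipped hinges, one ≈ 11 cm tension-only tendon per distal joint,
zero-force guides, semi-implicit Euler at 0.005 s) in reduced coordinates
with the pleating-axis and attachment conventions documented above.
General-purpose compliant-constraint engines assemble the same ingredients
with different constraint handling and solver parameters, and this class
of system is chaotic, so dynamical outcomes are implementation-sensitive.
Consequences worth knowing:

* The closed-form energetics (flat-state energies, landscape minima,
  tendon sizing) are properties of the geometry alone and are
  backend-independent.
* Absolute dynamical quantities are not expected to transfer
  digit-for-digit between implementations.  In this backend the barrier
  crossing is inertial rather than quasi-static, so folding times at the
  reference cells are seconds rather than hundreds of seconds, and fewer
  `(k, l_r)` cells sustain the strict 175°-for-1 s folded criterion (the
  folded basin beyond the tendon's slack angle is a flat energy floor, so
  completion relies on momentum and the absorbing fold stop).  Fold
  success is not strictly monotone in torque for the same reason, and
  individual cell outcomes are sensitive to numerical detail (a cell
  simulated alone may differ from the same cell inside a sweep batch;
  each exposed entry point is itself deterministic).
* The unfolding feasibility map is robust: unfolding succeeds for long
  resting lengths and low stiffness, fails where stiff short tendons
  out-pull the 100 N·cm torque budget, and one stiff corner stalls
  numerically.
* Energy ordering (`U_a > U_c > U_b`, `E_ab < E_bc`) and the bistable
  lock are robust properties of the model, not tuned outcomes.
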