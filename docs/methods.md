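# Methods

## Constitutive model

The muscle is an incompressible, transversely isotropic, hyperelastic
composite.  Units are mm / N / MPa / s throughout; gravity and inertia are
neglected (quasi-static increments).

* **Volumetric term** `U_V = κ (J − 1)` with κ = 2 MPa.  The coefficient is
  exposed (`MuscleParams.kappa_vol`) because its physical role is that of a
  penalty remnant: its gradient `κ J C⁻¹` is balanced exactly by the
  incompressibility multiplier, whose rest value is −κ/2 = −1.
* **Isotropic matrix** (Humphrey): `U_I = c (exp(b(Ĩ_C − 3)) − 1)` with
  c = 3.795·10⁻⁴ MPa, b = 23.46.  The stress contribution is
  `2bc e^{b(Ĩ_C−3)} (J^{−2/3} I − Ĩ_C/3 C⁻¹)`; the `J^{−2/3}` factor is the
  one the chain rule produces from `Ĩ_C = J^{−2/3} tr C`, and it is the form
  that passes the central-difference energy check to 10⁻⁵ relative on 100
  random states (see `tests/test_acceptance.py`).
* **Fibers** (Hill-type): passive factor
  `f_PE = 2aA e^{a(λ̃_f−1)²}(λ̃_f−1)` for λ̃_f > 1 (A = 8.568·10⁻⁴,
  a = 12.43), force–length parabola `f_LCE` on [0.5, 1.5], force–velocity
  factor `f_VCE` (zero at or below −10 s⁻¹, arctangent in between, plateau
  `π/(4 atan 5)+1` above +2 s⁻¹), maximum nominal stress T₀ᴹ = 0.535 MPa.
  Two fiber populations (fast FG / slow SO) mix by cross-sectional area
  fraction; defaults μ_FG = 0.58 / μ_SO = 0.42 (a young adult biceps).
* **Activation**: first-order dynamics driven by constant neural excitation
  u; rate constant `k = u/τ_rise + (1−u)/τ_fall`, steady state
  `α_ss = (u/τ_rise + α_min (1−u)/τ_fall)/k`.  The minimum activation α_min
  is set to 0, which reproduces the familiar saturation value α = 0.91 at
  u = 0.5 with τ = 0.02/0.2 s.  Fiber-type constants: τ = 0.1/1.0 s (FG),
  0.3/3.0 s (SO).  Deactivation (u switched off mid-run) is out of scope.
* **Rate handling**: λ̃̇_f is a first-order backward difference over the
  time increment (the sign convention is negative in shortening).  The
  force–velocity factor enters the energy and the stress parametrically
  (it is not varied with strain in the constitutive relation): the
  contractile energy integrates `f_LCE` over λ̃_f with `f_VCE` frozen at the
  current rate, and `∂U_f/∂λ̃_f` is then exactly the mixed nominal stress.
* **Bone / tendon**: Saint Venant–Kirchhoff, `S = λ_m tr(E) I + 2μE`;
  bone μ = 6154, λ_m = 9231 MPa; tendon μ = 56, λ_m = 9296 MPa.  Note the
  tendon parameters imply near-incompressibility (ν ≈ 0.497), which has
  geometric consequences discussed below.

## Discretisation and solver

Linear tetrahedra (P1 displacements), one quadrature point; total-Lagrangian
kinematics with the large-deformation strain–displacement operator.
Incompressibility of the muscle is enforced weakly through `W = J² − 1` with
element-constant multipliers; constraint rows are scaled by the element
reference volume.

Three stabilisations make this mixed pair practical on structured tet
meshes:

1. **Mean dilatation (multiplier grouping).**  The raw one-multiplier-per-tet
   field is not inf-sup stable: local pressure checkerboards make the
   Newton systems nearly singular.  The flexion scenarios therefore share
   one multiplier per six-tet hex patch (exact per-patch volume
   conservation); the hook is `Model(multiplier_groups=...)`, and the raw
   per-element field remains the default for single-element and
   unit-fixture work, where it is stable and exact.
2. **Augmented Lagrangian.**  A penalty stress `k (J²−1) dW/dE` with
   k = 4·10⁴ MPa (scenario default) is added per element.  It vanishes
   identically once the constraint holds, so converged solutions are
   unchanged, but it keeps the displacement block positive on volumetric
   modes and bounds the per-element |J−1| between the grouped constraints.
   Measured over all four studies the worst per-element |J−1| is below
   10⁻³.
3. **Perturbed multiplier block.**  A small diagonal `−ε V` (ε = 10⁻⁴/MPa)
   regularises the multiplier equations; the induced volume error is
   `|J−1| ~ ε|m − m_rest|/2`, orders of magnitude below the 10⁻³ contract.

The consistent tangent is numerical: a central finite difference of the
(augmented) stress with respect to the Green–Lagrange strain in engineering
Voigt measures (perturbation 10⁻⁷), batched over all elements, plus the
exact geometric stiffness and the exact displacement–multiplier coupling.
Inside this tangent the backward-difference rate is differentiated
consistently — without that coupling Newton cycles on a fixed point whenever
`(∂T/∂λ̃̇_f)/Δt` is comparable to the material stiffness.  The point-wise
`material_tangent` utility keeps the force–velocity factor frozen, matching
the constitutive convention.

Newton uses an affine-invariant (natural) monotonicity line search: trial
residuals are measured through the factorised Jacobian inverse, which
rescales the stiff bone rows and tolerates the strong curvature of the
exponential matrix term.  The factorisation is reused for up to four
iterations (modified Newton) and rebuilt when step quality degrades.
Safeguards: element-inversion rejection, an optional trust-region cap on the
per-iteration nodal displacement (2 mm in the scenarios), and a multiplier
plausibility bound that classifies spuriously pressurised roots as
non-convergence.  Convergence is relative (10⁻⁶ for scenario runs, 10⁻⁹–10⁻¹⁰
for the validation fixtures) with an absolute floor of 10⁻⁸ N set by the
round-off of the stiff bone terms.  Dirichlet conditions are eliminated;
point loads are split equally over the named node set.

Time marching solves a quasi-static increment per step (default
dt = 0.01 s).  On failure the (activation, load) increment is bisected with
a proportionally scaled time increment — dt halving generalised to
discontinuous load schedules.  A small dynamic-relaxation term
`c V_node (u − u_prev)/Δt` with c = 2·10⁻⁶ MPa·s/mm regularises the
near-mechanism transient when the dumbbell load is applied to the
still-passive arm; during the slow, near-equilibrium phase that determines
the peak angles the associated forces are fractions of a newton (halving c
changes the trajectories imperceptibly), and c = 0 recovers pure
quasi-statics (used in all validation fixtures).

## Synthetic forearm geometry

The CT-derived geometry of a real forearm is not available, so the
scenarios run on a generated idealisation (everything structured,
conforming, deterministic):

* a slender prismatic **radius** (square section, half-width 5 mm, length
  250 mm) along +X, pinned at the origin (the elbow hinge: the single
  proximal node is fully fixed, and Y displacement is blocked within 10% of
  both ends to suppress supination, leaving rotation about +Y free);
* a **muscle–tendon chain** hanging vertically above the insertion point at
  a quarter of the radius length: proximal tendon strap (fixed top face,
  standing in for the humeral attachment), fusiform body (sinusoidal radius
  profile, 24 → 31 mm, squircle-mapped sections), distal strap morphing to
  the bone's square section;
* the distal tendon meets the bone along a single transverse **line of
  shared nodes** (a piano hinge, like the narrow ridge of a tuberosity
  insertion).  An earlier face-welded variant was rejected: with the
  nearly incompressible tendon a welded patch acts as a moment bracket
  whose couple (measured at ~2·10⁴ N·mm) locks the elbow;
* the outer 15% of the fusiform body at each end is labelled tendon
  (aponeurosis); the contractile muscle region is the belly between the
  myotendinous junctions.  This keeps the active region away from the
  attachment stress concentrations, where per-element incompressibility
  would otherwise be violated by the kinematic limits of linear tets.

Cells come from Kuhn (Freudenthal) six-tet splitting of structured hex
grids, which is conforming across cells and across the insertion line.  The
default density (axial spacing 18 mm, 5-node sections) gives 2880 tets and
945 nodes; region volumes match the generative solids to better than 1%
(the 16-gon sections are the generative shapes — integrated by fine axial
quadrature) and the minimum dihedral angle is above the documented 5°
floor.

**Sizing rationale** (chosen from statics, before any study): holding the
100 N dumbbell at the tip requires ≈ 400 N along the muscle line
(250 mm / 62.5 mm lever).  The belly cross-sections were sized so the peak
active capacity `T₀ᴹ · 0.91 · A` exceeds that by roughly 1.7×, placing the
neural-excitation threshold near u = 0.2 (capacity crosses the requirement
between u = 0.1 and u = 0.2) and keeping the weakest strength case
(0.7 T₀ᴹ) above the requirement so the strength sweep stays strictly
monotone.  Two effects discovered during development shaped the profile:
a fat fusiform bulge acts as a muscular hydrostat (fiber tension is
consumed pressurising the bulge instead of being transmitted), and the
slimmest muscle section caps the transmitted force — hence the
near-cylindrical belly.

## The studies

All scenario runs are deterministic (no randomness anywhere in the solve).

* **Velocity study**: linear activation ramps to α = 0.91 peaking at 0.05,
  0.20 and 1.00 s, with the load ramped in proportion to activation up to
  100 N.  Each case runs to its activation peak with dt = min(0.01,
  t_peak/20).  A rate-independent quasi-static model has a unique long-time
  equilibrium, so the force–velocity effect is transient by construction;
  the angle achieved when activation peaks is the meaningful outcome and
  reproduces the slower-is-stronger ordering.
* **Sarcopenia studies** (composition 58/51/44% fast-twitch; strength scale
  1.0–0.7; excitation u = 0.5–0.1): first-order activation dynamics with
  the fiber-type time constants, 100 N load held constant after a 0.4 s
  application ramp, window 1.0 s (matching the roughly one-second span of
  published flexion trajectories).  Applying the full load to the inactive arm in a single
  quasi-static step would first drop it through a deep passive sag — the
  ramp bounds the increments; the peak angles are reached much later and
  are insensitive to the application window.
* Peak-angle slopes are ordinary least squares on (parameter, peak angle),
  reported per 10% of the swept parameter (10 percentage points of
  fast-twitch fraction, 0.1 of the T₀ᴹ scale, 0.1 of u); the excitation
  study fits the segments above and below u = 0.2 separately.

What the synthetic geometry does and does not show: the *orderings*
(velocity, composition, strength, excitation), the near-linearity of the
composition and strength responses, and the excitation threshold are
properties of the muscle model and carry over; the angle *magnitudes*
depend on the lever geometry, muscle cross-section and passive support and
are not comparable to any specific anatomy.  The model contains a single
elbow flexor and no joint contact, so motions involving other muscle groups
cannot be represented.

## Validation

* Single-element and 6-tet-cube uniaxial passive stretch (λ up to 1.3) and
  isometric activation (α up to 0.91) against the 1D incompressible
  material-point solution (transverse stretch λ^{−1/2}, multiplier from the
  zero-transverse-stress condition): agreement to 0.05%, far inside the 1%
  bound; the isometric nominal stress at α = 0.91 is 0.535·0.91 ≈ 0.487 MPa.
* Energy–stress consistency: the analytic second Piola–Kirchhoff stress
  matches the central difference of `U + m W` to 10⁻⁵ relative on 100
  random near-isochoric states.
* The harmonic fiber potential is exactly linear on a straight cylinder
  (nodal error ≤ 10⁻⁸) with directions within 10⁻⁶ rad of the axis.

## Known limitations

* P1/P0 with element-wise constraints is not inf-sup stable; the grouped
  (mean-dilatation) variant used by the scenarios trades exact per-element
  volume conservation for stability and recovers it through the
  augmentation penalty (measured |J−1| < 10⁻³ everywhere, but this is
  penalty-controlled, not exact).
* Volumetric locking stiffens bending-dominated muscle deformation; angle
  magnitudes are therefore conservative.
* The series element of the Hill model carries the contractile stress
  unchanged (no separate series constitutive law); activation history
  beyond the first-order dynamics, fatigue, EMG-derived excitation and
  muscle–bone contact are out of scope.
* Mesh I/O supports Gmsh MSH v2.2 ASCII and legacy VTK ASCII (node sets as
  point elements / flag arrays; regions as physical names / cell data).
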