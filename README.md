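# myoflex

Finite-element simulation of active skeletal-muscle mechanics, built around a
Hill-type transversely isotropic hyperelastic muscle model and an idealised
forearm (radius bone, biceps, tendons) that reproduces elbow-flexion
parametric studies: contraction velocity, fast/slow-twitch fiber composition,
maximum muscle strength and neural excitation — the three factors whose
decline characterises sarcopenia.

## The model

The muscle is an incompressible fiber-reinforced composite with strain
energy

    U = U_V + U_I + U_f
    U_V = 2 (J − 1)
    U_I = c [exp(b (Ĩ_C − 3)) − 1],   Ĩ_C = J^(−2/3) tr C
    U_f = U_PE(λ̃_f) + U_CE(λ̃_f; λ̃̇_f, α)

where `C = FᵀF`, `J = det F`, and `λ̃_f` is the isochoric stretch along the
reference fiber direction `N_m`.  The fiber stress follows the Hill
three-element picture: a passive parallel element

    f_PE(λ̃_f) = 2 a A exp(a (λ̃_f − 1)²)(λ̃_f − 1)   for λ̃_f > 1, else 0

and an active contractile element `T_CE = T₀ᴹ f_LCE(λ̃_f) f_VCE(λ̃̇_f) α(t)`
with the parabola `f_LCE = 1 − 4 (λ̃_f − 1)²` on [0.5, 1.5] and an
arctangent force–velocity factor that vanishes at shortening rates beyond
−10 s⁻¹.  Fast- (FG) and slow-twitch (SO) fiber populations share the
kinematics and mix by cross-sectional area fractions μ_FG, μ_SO, each with
its own activation level driven by neural excitation u ∈ [0, 0.5] through
first-order dynamics with rise/fall constants τ — with u = 0.5,
τ_rise = 0.02 s, τ_fall = 0.2 s the activation saturates at α = 0.91.
Bone and tendon are Saint Venant–Kirchhoff solids.

Incompressibility (W = J² − 1 = 0) is enforced with Lagrange multipliers in
a mixed total-Lagrangian formulation on linear tetrahedra (one quadrature
point, element-wise constant multipliers, augmented-Lagrangian
stabilisation), solved quasi-statically by damped Newton with a numerically
differentiated consistent tangent.  Muscle fiber directions come from a
Laplace problem between the tendon attachment surfaces (the normalised
potential gradient per element).

## Worked example

```python
from myoflex import ScenarioConfig
from myoflex.scenarios import forearm_model_inputs, run_composition_study

config = ScenarioConfig()
mesh, fibers = forearm_model_inputs(config)
result = run_composition_study(config, mesh=mesh, fibers=fibers)
print(result.summary_frame())
print(f"slope: {result.slope_per_10pct:.2f} deg per 10% fast-twitch, "
      f"R^2 = {result.r2:.3f}")
```

prints (synthetic geometry, defaults; about five minutes on one CPU):

```
   parameter  peak_angle_deg  onset_time_s
0       58.0       13.870528          0.03
1       51.0       13.790201          0.03
2       44.0       13.708048          0.03
slope: 0.12 deg per 10% fast-twitch, R^2 = 1.000
```

The peak elbow-flexion angle increases strictly with the fast-twitch
percentage (58% is a young adult, 51% and 44% are elderly compositions)
and the relationship is almost perfectly linear.  Angle magnitudes are
specific to the synthetic geometry — the orderings and the linearity are
the transferable result.

The same can be run from a shell:

```bash
myoflex run --study composition --out results/
myoflex validate            # uniaxial FE vs material-point check
myoflex mesh --kind forearm --out forearm.msh
myoflex fibers --mesh forearm.msh --out fibers.vtk
```

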