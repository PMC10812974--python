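"""Total-Lagrangian FE core: kinematics, assembly, Newton, time marching."""

import numpy as np
import pytest

from myoflex import fem_core as fc
from myoflex import scenarios as sc
from myoflex.fem_core import (
    DirichletBC,
    LoadCase,
    Model,
    SolverSettings,
    assemble_system,
    element_kinematics,
    newton_solve,
    strain_displacement_matrix,
    time_march,
)
from myoflex.activation import ActivationProfile
from myoflex.materials import (
    ActivationPair,
    MuscleParams,
    SingularDeformationError,
)
from myoflex.geometry_fixtures import make_unit_fixture


QUASISTATIC = SolverSettings(dt=1e9, tolerance=1e-10)


def uniaxial_case(stretch):
    return LoadCase(dirichlet=[
        DirichletBC("x0", (0,), 0.0),
        DirichletBC("x1", (0,), stretch - 1.0),
        DirichletBC("y0", (1,), 0.0),
        DirichletBC("z0", (2,), 0.0),
    ])


# ---------------------------------------------------------------------------
# Element operators
# ---------------------------------------------------------------------------

def test_element_kinematics_rigid_and_affine(rng):
    coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    assert np.allclose(element_kinematics(coords, np.zeros((4, 3))), np.eye(3))
    assert np.allclose(
        element_kinematics(coords, np.tile([0.3, -0.1, 2.0], (4, 1))), np.eye(3)
    )
    A = 0.1 * rng.standard_normal((3, 3))
    disp = coords @ A.T
    assert np.allclose(element_kinematics(coords, disp), np.eye(3) + A, atol=1e-12)


def test_strain_displacement_matrix_matches_fd(rng):
    coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    disp = 0.05 * rng.standard_normal((4, 3))
    B = strain_displacement_matrix(coords, disp)

    def green(u):
        F = element_kinematics(coords, u)
        E = 0.5 * (F.T @ F - np.eye(3))
        return np.array([E[0, 0], E[1, 1], E[2, 2],
                         2 * E[0, 1], 2 * E[1, 2], 2 * E[0, 2]])

    h = 1e-7
    for _ in range(4):
        du = rng.standard_normal(12)
        fd = (green(disp + h * du.reshape(4, 3)) - green(disp - h * du.reshape(4, 3))) / (2 * h)
        assert np.max(np.abs(B @ du - fd)) <= 1e-6


# ---------------------------------------------------------------------------
# Assembly and rest state
# ---------------------------------------------------------------------------

def test_rest_state_residual_vanishes(params):
    mesh = make_unit_fixture("unit_cube", 1)
    model = Model(mesh, {"muscle": params}, LoadCase(), settings=QUASISTATIC)
    st = model.new_state()
    assert st.multiplier[0] == pytest.approx(-1.0)
    R, _ = assemble_system(model, st.u, st.multiplier,
                           ActivationPair.uniform(0.0), st.lambda_f_prev,
                           1e9, 0.0, with_tangent=False)
    assert np.linalg.norm(R) <= 1e-10


def test_inverted_element_diagnostic(params):
    mesh = make_unit_fixture("unit_cube", 1)
    model = Model(mesh, {"muscle": params}, LoadCase(), settings=QUASISTATIC)
    st = model.new_state()
    u = st.u.copy()
    u.reshape(-1, 3)[:, 0] = -2.0 * mesh.points[:, 0]  # fold the cube over
    with pytest.raises(SingularDeformationError):
        assemble_system(model, u, st.multiplier, ActivationPair.uniform(0.0),
                        st.lambda_f_prev, 1e9, 0.0)


def test_zero_load_converges_immediately(params):
    mesh = make_unit_fixture("unit_cube", 1)
    model = Model(mesh, {"muscle": params},
                  LoadCase(dirichlet=[DirichletBC("x0", (0, 1, 2), 0.0)]),
                  settings=QUASISTATIC)
    out = newton_solve(model, model.new_state(), ActivationPair.uniform(0.0),
                       0.0, dt=1e9)
    assert out.iterations <= 1
    assert np.allclose(out.u, 0.0)


# ---------------------------------------------------------------------------
# Single-element and patch checks against the material point
# ---------------------------------------------------------------------------

def test_passive_uniaxial_matches_1d_oracle(params):
    mesh = make_unit_fixture("single_tet")
    for lam in (1.1, 1.25):
        fe = sc._uniaxial_fe(mesh, params, lam, ActivationPair.uniform(0.0))
        oracle = sc.uniaxial_oracle(lam, ActivationPair.uniform(0.0), params)
        assert fe == pytest.approx(oracle, rel=0.01)


def test_patch_homogeneous_deformation(params):
    """A cube under affine isochoric boundary displacement stays affine."""
    lam = 1.08
    mesh = make_unit_fixture("unit_cube", 1)
    lc = LoadCase(dirichlet=[
        DirichletBC("x0", (0,), 0.0), DirichletBC("x1", (0,), lam - 1.0),
        DirichletBC("y0", (1,), 0.0), DirichletBC("y1", (1,), lam**-0.5 - 1.0),
        DirichletBC("z0", (2,), 0.0), DirichletBC("z1", (2,), lam**-0.5 - 1.0),
    ])
    model = Model(mesh, {"muscle": params}, lc, settings=QUASISTATIC)
    out = newton_solve(model, model.new_state(), ActivationPair.uniform(0.3),
                       0.0, dt=1e9)
    F = model.deformation_gradients(out.u)
    F_exact = np.diag([lam, lam**-0.5, lam**-0.5])
    assert np.max(np.abs(F - F_exact)) <= 1e-8


def test_newton_superlinear_convergence(params):
    mesh = make_unit_fixture("single_tet")
    model = Model(mesh, {"muscle": params}, uniaxial_case(1.05),
                  settings=SolverSettings(dt=1e9, tolerance=1e-10,
                                          tangent_refresh=1))
    out = newton_solve(model, model.new_state(), ActivationPair.uniform(0.0),
                       0.0, dt=1e9)
    res = [r for r in out.residuals if r > 0.0]
    assert res[-1] <= 1e-3 * res[-2]
    assert res[-2] <= 0.2 * res[-3]


def test_mesh_refinement_end_force_agreement(params):
    """Passive stretch of the coarse and refined unit cube agree in stress."""
    vals = []
    for sub in (1, 2):
        mesh = make_unit_fixture("unit_cube", sub)
        vals.append(sc._uniaxial_fe(mesh, params, 1.2, ActivationPair.uniform(0.0)))
    assert vals[1] == pytest.approx(vals[0], rel=0.02)


def test_element_reordering_invariance(params, rng):
    mesh = make_unit_fixture("unit_cube", 1)
    perm = rng.permutation(mesh.n_elements)
    mesh2 = fc.Mesh(mesh.points, mesh.cells[perm], mesh.region[perm],
                    mesh.node_sets)
    u1 = _solve_uniaxial_displacement(mesh, params)
    u2 = _solve_uniaxial_displacement(mesh2, params)
    assert np.allclose(u1, u2, atol=1e-8)


def _solve_uniaxial_displacement(mesh, params):
    model = Model(mesh, {"muscle": params}, uniaxial_case(1.1),
                  settings=QUASISTATIC)
    state = model.new_state()
    for f in (0.5, 1.0):
        state = newton_solve(model, state, ActivationPair.uniform(0.0), 0.0,
                             dt=1e9, dirichlet_factor=f)
    return state.u


# ---------------------------------------------------------------------------
# Time marching
# ---------------------------------------------------------------------------

def _isometric_model(params):
    mesh = make_unit_fixture("single_tet")
    lc = LoadCase(dirichlet=[
        DirichletBC("x0", (0,), 0.0), DirichletBC("x1", (0,), 0.0),
        DirichletBC("y0", (1,), 0.0), DirichletBC("z0", (2,), 0.0),
    ])
    return mesh, Model(mesh, {"muscle": params}, lc,
                       settings=SolverSettings(dt=0.01, tolerance=1e-10))


def test_time_march_stays_at_rest(params):
    _, model = _isometric_model(params)
    states = time_march(model, model.new_state(),
                        lambda t: ActivationPair.uniform(0.0), 0.05)
    for stt in states:
        assert np.allclose(stt.u, 0.0, atol=1e-12)


def test_isometric_stress_tracks_activation(params):
    """Both ends fixed: fiber stress follows T0M * alpha(t) exactly."""
    mesh, model = _isometric_model(params)
    prof = ActivationProfile(kind="linear_ramp", t_peak=0.1, alpha_max=0.91)
    states = time_march(model, model.new_state(),
                        lambda t: ActivationPair.uniform(float(prof(t))), 0.1)
    for stt in states:
        fe = _fiber_stress_of_state(model, stt, params,
                                    ActivationPair.uniform(float(prof(stt.t))))
        assert fe == pytest.approx(params.t0m * float(prof(stt.t)), rel=1e-4, abs=1e-10)


def _fiber_stress_of_state(model, state, params, act):
    F = model.deformation_gradients(state.u)
    C = np.swapaxes(F, 1, 2) @ F
    S = fc._muscle_stress_aug(C, model.fibers, 1.0, act, params,
                              state.multiplier[model.multiplier_groups],
                              model.settings.augmentation_stiffness)
    P = F @ S
    return float(np.average(P[:, 0, 0], weights=model.V))


def test_time_step_refinement(params):
    """Halving dt changes the final isometric state negligibly."""
    mesh, _ = _isometric_model(params)
    prof = ActivationProfile(kind="linear_ramp", t_peak=0.2, alpha_max=0.91)
    finals = []
    for dt in (0.02, 0.01):
        lc = LoadCase(dirichlet=[
            DirichletBC("x0", (0,), 0.0), DirichletBC("x1", (0,), 0.0),
            DirichletBC("y0", (1,), 0.0), DirichletBC("z0", (2,), 0.0),
        ])
        model = Model(mesh, {"muscle": params}, lc,
                      settings=SolverSettings(dt=dt, tolerance=1e-10))
        states = time_march(model, model.new_state(),
                            lambda t: ActivationPair.uniform(float(prof(t))), 0.2)
        finals.append(states[-1].u.copy())
    ref = max(np.max(np.abs(finals[1])), 1e-12)
    assert np.max(np.abs(finals[0] - finals[1])) <= 0.01 * max(ref, 1e-6)


def test_incompressibility_under_active_contraction(params):
    """Free contraction of a cube keeps every element's J near one."""
    mesh = make_unit_fixture("unit_cube", 1)
    lc = LoadCase(dirichlet=[
        DirichletBC("x0", (0,), 0.0),
        DirichletBC("y0", (1,), 0.0), DirichletBC("z0", (2,), 0.0),
    ])
    model = Model(mesh, {"muscle": params}, lc,
                  settings=SolverSettings(dt=0.01, tolerance=1e-9))
    prof = ActivationProfile(kind="linear_ramp", t_peak=0.1, alpha_max=0.5)
    states = time_march(model, model.new_state(),
                        lambda t: ActivationPair.uniform(float(prof(t))), 0.1)
    for stt in states:
        J, _ = model.muscle_J_lambda(stt.u)
        assert np.max(np.abs(J - 1.0)) <= 1e-3
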