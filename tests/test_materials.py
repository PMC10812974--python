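"""Constitutive-law unit tests: Hill-type factors, stresses, energies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from myoflex import materials as M
from tests.conftest import random_muscle_states


# ---------------------------------------------------------------------------
# 1D Hill factors
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("lam, expected", [
    (1.0, 0.0),
    (0.9, 0.0),
    # direct evaluation of 2 a A exp(a (0.1)^2) * 0.1 with printed a, A
    (1.1, 2.0 * 12.43 * 8.568e-4 * np.exp(12.43 * 0.01) * 0.1),
])
def test_passive_fiber_factor(lam, expected, params):
    assert M.f_PE(lam, params) == pytest.approx(expected, abs=1e-15)


def test_passive_fiber_factor_monotone_above_one(params):
    lams = np.linspace(1.0, 1.5, 100)
    vals = M.f_PE(lams, params)
    assert np.all(np.diff(vals) > 0.0)
    assert vals[0] == 0.0


@pytest.mark.parametrize("lam, expected", [
    (1.0, 1.0), (1.5, 0.0), (0.5, 0.0), (1.25, 0.75), (0.49, 0.0), (1.51, 0.0),
])
def test_force_length_factor(lam, expected):
    assert M.f_LCE(lam) == pytest.approx(expected, abs=1e-14)


@pytest.mark.parametrize("rate, expected", [
    (-12.0, 0.0),
    (0.0, 1.0),
    (2.0, np.pi / (4.0 * np.arctan(5.0)) + 1.0),
    (5.0, np.pi / (4.0 * np.arctan(5.0)) + 1.0),
])
def test_force_velocity_factor(rate, expected):
    assert M.f_VCE(rate) == pytest.approx(expected, abs=1e-14)


def test_force_velocity_branch_continuity():
    mid = lambda v: -np.arctan(-0.5 * v) / np.arctan(5.0) + 1.0
    assert abs(mid(-10.0) - 0.0) <= 1e-12
    assert abs(mid(2.0) - M.F_VCE_MAX) <= 1e-12


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(-20, 10), st.floats(-20, 10))
def test_force_velocity_nondecreasing_and_bounded(a, b):
    lo, hi = sorted((a, b))
    assert M.f_VCE(lo) <= M.f_VCE(hi) + 1e-15
    assert 0.0 <= M.f_VCE(a) <= M.F_VCE_MAX


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def test_kinematics_reference_state():
    kin = M.kinematics_from_F(np.eye(3), [1.0, 0, 0], lambda_f_prev=1.0, dt=0.1)
    assert kin.J == pytest.approx(1.0)
    assert kin.lambda_f == pytest.approx(1.0)
    assert kin.lambda_f_dot == pytest.approx(0.0)


def test_kinematics_isochoric_uniaxial():
    lam = 1.2
    F = np.diag([lam, lam**-0.5, lam**-0.5])
    kin = M.kinematics_from_F(F, [1.0, 0, 0])
    assert kin.J == pytest.approx(1.0)
    assert kin.lambda_f == pytest.approx(1.2)


def test_kinematics_dilation_invariance():
    # pure dilation: J = 8, J^(-2/3) tr C = 12/4 = 3, fiber stretch 1
    kin = M.kinematics_from_F(2.0 * np.eye(3), [0.0, 0, 1.0])
    assert kin.J == pytest.approx(8.0)
    assert kin.I_tilde_C == pytest.approx(3.0)
    assert kin.lambda_f == pytest.approx(1.0)


def test_kinematics_rejects_inverted_state():
    F = np.stack([np.eye(3), -np.eye(3)])
    with pytest.raises(M.SingularDeformationError) as err:
        M.kinematics_from_F(F, np.array([[1.0, 0, 0]] * 2), np.ones(2), 0.1,
                            element_ids=[7, 9])
    assert 9 in err.value.elements


def test_backward_difference_rate():
    F = np.diag([1.1, 1.1**-0.5, 1.1**-0.5])
    kin = M.kinematics_from_F(F, [1.0, 0, 0], lambda_f_prev=1.0, dt=0.05)
    assert kin.lambda_f_dot == pytest.approx((1.1 - 1.0) / 0.05)


# ---------------------------------------------------------------------------
# Nominal fiber stress and the two-population mixture
# ---------------------------------------------------------------------------

def test_isometric_fiber_stress_single_population(params):
    p = params.with_fast_fraction(1.0)
    kin = M.kinematics_from_F(np.eye(3), [1.0, 0, 0])
    act = M.ActivationPair(alpha_so=0.0, alpha_fg=0.91)
    assert M.fiber_nominal_stress(kin, act, p) == pytest.approx(0.535 * 0.91)


def test_no_activation_no_stretch_gives_zero(params):
    kin = M.kinematics_from_F(np.eye(3), [1.0, 0, 0])
    assert M.fiber_nominal_stress(kin, M.ActivationPair.uniform(0.0), params) == 0.0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(0.6, 1.4), st.floats(-5, 3), st.floats(0, 1), st.floats(0, 1))
def test_mixture_reduces_to_single_population(lam, rate, alpha, mu_fg):
    """Equal activations collapse the mixture to the one-population law."""
    p = M.MuscleParams().with_fast_fraction(mu_fg)
    single = p.t0m * (M.f_PE(lam, p) + M.f_LCE(lam) * M.f_VCE(rate) * alpha)
    mixed = M._nominal_stress(lam, M.f_VCE(rate), M.ActivationPair.uniform(alpha), p)
    assert mixed == pytest.approx(single, abs=1e-14)


def test_mixture_fractions_validated():
    with pytest.raises(ValueError):
        M.MuscleParams(mu_so=0.5, mu_fg=0.6)


# ---------------------------------------------------------------------------
# Strain energy
# ---------------------------------------------------------------------------

def test_energy_zero_at_reference(params):
    kin = M.kinematics_from_F(np.eye(3), [1.0, 0, 0])
    assert M.muscle_strain_energy(kin, M.ActivationPair.uniform(0.0), params) == 0.0


def test_passive_energy_closed_forms(params):
    """Isochoric fiber stretch: matrix + passive-fiber closed forms."""
    lam = 1.1
    F = np.diag([lam, lam**-0.5, lam**-0.5])
    kin = M.kinematics_from_F(F, [1.0, 0, 0])
    i_c = lam**2 + 2.0 / lam
    u_matrix = params.c * (np.exp(params.b * (i_c - 3.0)) - 1.0)
    u_pe = params.t0m * params.A * (np.exp(params.a * (lam - 1.0) ** 2) - 1.0)
    u = M.muscle_strain_energy(kin, M.ActivationPair.uniform(0.0), params)
    assert u == pytest.approx(u_matrix + u_pe, rel=1e-10)
    # the printed-constant magnitudes behind the closed forms
    assert params.c * (np.exp(params.b * 0.1) - 1.0) == pytest.approx(3.584e-3, rel=1e-3)
    assert u_pe == pytest.approx(6.066e-5, rel=1e-3)


def test_active_energy_integral(params):
    """CE energy equals alpha T0M f_VCE times the force-length integral."""
    lam, rate, alpha = 0.9, -1.0, 0.6
    F = np.diag([lam, lam**-0.5, lam**-0.5])
    kin = M.kinematics_from_F(F, [1.0, 0, 0], lambda_f_prev=lam - rate * 0.1, dt=0.1)
    g, _ = quad(M.f_LCE, 1.0, lam)
    expected = alpha * params.t0m * float(M.f_VCE(kin.lambda_f_dot)) * g
    u = M.muscle_strain_energy(kin, M.ActivationPair.uniform(alpha), params)
    u0 = M.muscle_strain_energy(kin, M.ActivationPair.uniform(0.0), params)
    assert u - u0 == pytest.approx(expected, rel=1e-9)


# ---------------------------------------------------------------------------
# Second Piola-Kirchhoff stress
# ---------------------------------------------------------------------------

def test_rest_state_stress_free_at_rest_multiplier(params):
    kin = M.kinematics_from_F(np.eye(3), [1.0, 0, 0])
    S = M.muscle_second_pk(kin, M.ActivationPair.uniform(0.0), params,
                           multiplier=-1.0)
    assert np.allclose(S, 0.0, atol=1e-14)


def test_stress_objectivity(params, rng):
    for F, N in random_muscle_states(rng, 5):
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        kin1 = M.kinematics_from_F(F, N)
        kin2 = M.kinematics_from_F(R @ F, N)
        act = M.ActivationPair.uniform(0.5)
        S1 = M.muscle_second_pk(kin1, act, params, -1.0)
        S2 = M.muscle_second_pk(kin2, act, params, -1.0)
        assert np.allclose(S1, S2, atol=1e-12)


def test_stress_symmetry_and_energy_consistency(params, rng):
    """S equals the central difference of U + m W on random states."""
    h = 1e-6
    for F, N in random_muscle_states(rng, 12):
        kin = M.kinematics_from_F(F, N, lambda_f_prev=1.0, dt=0.1)
        act = M.ActivationPair.uniform(0.5)
        mult = -1.2
        fv = float(M.f_VCE(kin.lambda_f_dot))
        S = M.muscle_pk2_from_C(kin.C, N, fv, act, params, mult)
        assert np.allclose(S, S.T, atol=1e-12)
        S_fd = _energy_fd_stress(kin.E, N, fv, act, params, mult, h)
        assert np.max(np.abs(S - S_fd)) <= 1e-5 * max(np.max(np.abs(S)), 1e-8)


def _energy_fd_stress(E, N, fv_frozen, act, params, mult, h):
    """Independent oracle: central difference of the energy wrt E."""
    def psi(Emat):
        C = 2.0 * Emat + np.eye(3)
        J = np.sqrt(np.linalg.det(C))
        lam = float(np.sqrt(J ** (-2.0 / 3.0) * N @ C @ N))
        u = params.kappa_vol * (J - 1.0)
        u += params.c * (np.exp(params.b * (J ** (-2.0 / 3.0) * np.trace(C) - 3.0)) - 1.0)
        if lam > 1.0:
            u += params.t0m * params.A * (np.exp(params.a * (lam - 1.0) ** 2) - 1.0)
        g, _ = quad(M.f_LCE, 1.0, lam)
        u += float(act.mixed(params)) * params.t0m * fv_frozen * g
        return u + mult * (J**2 - 1.0)

    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            dE = np.zeros((3, 3))
            if i == j:
                dE[i, j] = h
            else:
                dE[i, j] = dE[j, i] = 0.5 * h
            S[i, j] = S[j, i] = (psi(E + dE) - psi(E - dE)) / (2.0 * h)
    return S


def test_stvk_stress_bone_values():
    E = np.diag([0.01, 0.0, 0.0])
    S = M.stvk_second_pk(E, M.BONE)
    assert S[0, 0] == pytest.approx(9231 * 0.01 + 2 * 6154 * 0.01)
    assert S[1, 1] == pytest.approx(92.31)
    assert S[2, 2] == pytest.approx(92.31)


def test_stvk_linearity(rng):
    E1 = rng.standard_normal((3, 3)); E1 = 0.01 * (E1 + E1.T)
    E2 = rng.standard_normal((3, 3)); E2 = 0.01 * (E2 + E2.T)
    S12 = M.stvk_second_pk(E1 + E2, M.TENDON)
    assert np.allclose(S12, M.stvk_second_pk(E1, M.TENDON) + M.stvk_second_pk(E2, M.TENDON))


# ---------------------------------------------------------------------------
# Numerical tangent
# ---------------------------------------------------------------------------

def test_material_tangent_matches_stvk_closed_form():
    D = M.material_tangent(lambda E: M.stvk_second_pk(E, M.BONE), np.zeros((3, 3)))
    assert np.allclose(D, M.stvk_tangent(M.BONE), atol=1e-4)


def test_muscle_tangent_symmetry_at_rest(params):
    def stress(E):
        C = 2.0 * E + np.eye(3)
        return M.muscle_pk2_from_C(C, np.array([1.0, 0, 0]), 1.0,
                                   M.ActivationPair.uniform(0.0), params, -1.0)

    D = M.material_tangent(stress, np.zeros((3, 3)))
    assert np.max(np.abs(D - D.T)) <= 1e-6 * max(np.max(np.abs(D)), 1.0)
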