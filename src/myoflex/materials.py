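"""Constitutive models for skeletal muscle, bone and tendon.

The muscle is modelled as an incompressible, transversely isotropic,
hyperelastic fiber-reinforced composite.  Its strain energy is the sum of

* a volumetric term ``kappa_vol * (J - 1)`` whose gradient is balanced by the
  incompressibility Lagrange multiplier (the rest-state multiplier is
  ``-kappa_vol / 2``),
* an isotropic matrix term (Humphrey type) ``c * (exp(b * (I~_C - 3)) - 1)``
  in the first reduced (isochoric) invariant ``I~_C = J^(-2/3) tr C``, and
* a fiber term built from a Hill-type three-element model: a passive parallel
  element and an active contractile element whose nominal stress is the
  product of a force-length factor ``f_LCE``, a force-velocity factor
  ``f_VCE`` and the activation level ``alpha``.

Fast-twitch and slow-twitch fiber populations share the same kinematics and
are mixed by their cross-sectional area fractions; each population carries its
own activation level.  Bone and tendon are Saint Venant-Kirchhoff (isotropic,
geometrically nonlinear) materials.

Units are mm / N / MPa / s throughout.  Stress functions return the second
Piola-Kirchhoff tensor, work-conjugate to the Green-Lagrange strain.  All
point-wise operations accept batched inputs (leading axes before the tensor
axes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ATAN5",
    "F_VCE_MAX",
    "MuscleParams",
    "IsotropicElasticParams",
    "BONE",
    "TENDON",
    "ActivationPair",
    "KinPoint",
    "SingularDeformationError",
    "DegenerateElementError",
    "kinematics_from_F",
    "f_PE",
    "f_LCE",
    "f_VCE",
    "fiber_nominal_stress",
    "muscle_strain_energy",
    "muscle_incompressible_energy",
    "muscle_second_pk",
    "muscle_pk2_from_C",
    "stvk_second_pk",
    "stvk_tangent",
    "material_tangent",
    "VOIGT_PAIRS",
    "sym_to_voigt",
    "voigt_to_sym",
]

ATAN5 = float(np.arctan(5.0))
#: Plateau value of the force-velocity factor for fast lengthening.
F_VCE_MAX = float(np.pi / (4.0 * ATAN5) + 1.0)

#: Voigt component ordering (11, 22, 33, 12, 23, 13).
VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2))


class SingularDeformationError(ValueError):
    """Deformation gradient with non-positive determinant."""

    def __init__(self, elements):
        self.elements = np.atleast_1d(np.asarray(elements))
        super().__init__(
            f"non-positive det(F) in element(s) {self.elements.tolist()}"
        )


class DegenerateElementError(ValueError):
    """Singular right Cauchy-Green tensor (degenerate element)."""

    def __init__(self, elements):
        self.elements = np.atleast_1d(np.asarray(elements))
        super().__init__(
            f"singular C in element(s) {self.elements.tolist()}"
        )


@dataclass(frozen=True)
class MuscleParams:
    """Constitutive constants of the muscle.

    Attributes
    ----------
    c, b:
        Isotropic matrix stiffness coefficient (MPa) and exponent.
    t0m:
        Maximum nominal fiber stress T0M (MPa).
    A, a:
        Passive-fiber coefficient and exponent (dimensionless).
    alpha_min:
        Minimum (resting) activation level.
    mu_so, mu_fg:
        Cross-sectional area fractions of slow-twitch (SO) and fast-twitch
        (FG) fibers; must sum to 1.
    tau_rise_so, tau_fall_so, tau_rise_fg, tau_fall_fg:
        Activation/deactivation time constants (s) per fiber population.
    u:
        Neural excitation, in [0, 0.5].
    kappa_vol:
        Coefficient of the volumetric energy ``kappa_vol * (J - 1)`` (MPa).
        The rest-state Lagrange multiplier is ``-kappa_vol / 2``.
    """

    c: float = 3.795e-4
    b: float = 23.46
    t0m: float = 0.535
    A: float = 8.568e-4
    a: float = 12.43
    alpha_min: float = 0.0
    mu_so: float = 0.42
    mu_fg: float = 0.58
    tau_rise_so: float = 0.3
    tau_fall_so: float = 3.0
    tau_rise_fg: float = 0.1
    tau_fall_fg: float = 1.0
    u: float = 0.5
    kappa_vol: float = 2.0

    def __post_init__(self) -> None:
        for name in ("c", "b", "t0m", "A", "a"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"MuscleParams.{name} must be > 0")
        if not (0.0 <= self.mu_so <= 1.0 and 0.0 <= self.mu_fg <= 1.0):
            raise ValueError("fiber fractions must lie in [0, 1]")
        if abs(self.mu_so + self.mu_fg - 1.0) > 1e-12:
            raise ValueError("mu_so + mu_fg must equal 1")
        for name in ("tau_rise_so", "tau_fall_so", "tau_rise_fg", "tau_fall_fg"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"MuscleParams.{name} must be > 0")
        if not 0.0 <= self.u <= 0.5:
            raise ValueError("neural excitation u must lie in [0, 0.5]")

    def with_fast_fraction(self, mu_fg: float) -> "MuscleParams":
        """Return a copy with the fast-twitch area fraction set to ``mu_fg``."""
        return replace(self, mu_fg=float(mu_fg), mu_so=1.0 - float(mu_fg))

    def scaled_strength(self, scale: float) -> "MuscleParams":
        """Return a copy with T0M scaled by ``scale`` (strength-decline sweeps)."""
        return replace(self, t0m=self.t0m * float(scale))


@dataclass(frozen=True)
class IsotropicElasticParams:
    """Saint Venant-Kirchhoff parameters: S = lame_lambda tr(E) I + 2 lame_mu E."""

    lame_lambda: float
    lame_mu: float

    def __post_init__(self) -> None:
        if self.lame_lambda <= 0.0 or self.lame_mu <= 0.0:
            raise ValueError("Lame parameters must be > 0")


#: Radius bone: mu = 6154 MPa, lambda_m = 9231 MPa.
BONE = IsotropicElasticParams(lame_lambda=9231.0, lame_mu=6154.0)
#: Tendon: mu = 56 MPa, lambda_m = 9296 MPa.
TENDON = IsotropicElasticParams(lame_lambda=9296.0, lame_mu=56.0)


@dataclass(frozen=True)
class ActivationPair:
    """Activation levels of the slow- and fast-twitch fiber populations."""

    alpha_so: float
    alpha_fg: float

    def __post_init__(self) -> None:
        a_so = np.asarray(self.alpha_so)
        a_fg = np.asarray(self.alpha_fg)
        if np.any(a_so < 0) or np.any(a_so > 1) or np.any(a_fg < 0) or np.any(a_fg > 1):
            raise ValueError("activation levels must lie in [0, 1]")

    @classmethod
    def uniform(cls, alpha) -> "ActivationPair":
        """Both fiber populations at the same activation level."""
        return cls(alpha_so=alpha, alpha_fg=alpha)

    def mixed(self, params: MuscleParams):
        """Area-fraction-weighted activation mu_SO*alpha_SO + mu_FG*alpha_FG."""
        return params.mu_so * np.asarray(self.alpha_so) + params.mu_fg * np.asarray(
            self.alpha_fg
        )


@dataclass(frozen=True)
class KinPoint:
    """Kinematic state at one (or a batch of) quadrature point(s).

    Holds the deformation gradient ``F``, its determinant ``J``, the right
    Cauchy-Green tensor ``C``, the Green-Lagrange tensor ``E``, the reduced
    invariant ``I~_C``, the isochoric fiber stretch ``lambda_f`` along the
    reference fiber direction ``N_m``, and its rate ``lambda_f_dot`` (1/s,
    negative during shortening).
    """

    F: np.ndarray
    J: np.ndarray
    C: np.ndarray
    E: np.ndarray
    I_tilde_C: np.ndarray
    lambda_f: np.ndarray
    lambda_f_dot: np.ndarray
    N_m: np.ndarray


def kinematics_from_F(F, N_m, lambda_f_prev=1.0, dt=1.0, element_ids=None) -> KinPoint:
    """Build a :class:`KinPoint` from a deformation gradient.

    ``lambda_f_dot`` is a first-order backward difference
    ``(lambda_f - lambda_f_prev) / dt``.  Raises
    :class:`SingularDeformationError` naming the offending element(s) when
    ``det F <= 0``.
    """
    F = np.asarray(F, dtype=float)
    N_m = np.asarray(N_m, dtype=float)
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    nrm = np.linalg.norm(N_m, axis=-1)
    if np.any(np.abs(nrm - 1.0) > 1e-9):
        raise ValueError("fiber direction N_m must be a unit vector")
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        bad = np.nonzero(np.atleast_1d(J) <= 0.0)[0]
        if element_ids is not None:
            bad = np.atleast_1d(np.asarray(element_ids))[bad]
        raise SingularDeformationError(bad)
    C = np.swapaxes(F, -1, -2) @ F
    eye = np.broadcast_to(np.eye(3), C.shape)
    E = 0.5 * (C - eye)
    Jm23 = J ** (-2.0 / 3.0)
    trC = np.trace(C, axis1=-2, axis2=-1)
    I_tilde = Jm23 * trC
    NCN = np.einsum("...i,...ij,...j->...", N_m, C, N_m)
    lam_f = np.sqrt(Jm23 * NCN)
    lam_dot = (lam_f - np.asarray(lambda_f_prev, dtype=float)) / dt
    return KinPoint(
        F=F, J=J, C=C, E=E, I_tilde_C=I_tilde,
        lambda_f=lam_f, lambda_f_dot=lam_dot, N_m=N_m,
    )


# ---------------------------------------------------------------------------
# Hill-type 1D factors
# ---------------------------------------------------------------------------

def f_PE(lambda_f, params: MuscleParams):
    """Passive parallel-element stress factor.

    ``2 a A exp(a (lambda_f - 1)^2) (lambda_f - 1)`` for ``lambda_f > 1``,
    zero otherwise.  Continuous at ``lambda_f = 1``.
    """
    lam = np.asarray(lambda_f, dtype=float)
    d = lam - 1.0
    val = 2.0 * params.a * params.A * np.exp(params.a * d * d) * d
    return np.where(lam > 1.0, val, 0.0)


def f_LCE(lambda_f):
    """Active force-length factor: ``-4 (lambda_f - 1)^2 + 1`` on [0.5, 1.5]."""
    lam = np.asarray(lambda_f, dtype=float)
    val = -4.0 * (lam - 1.0) ** 2 + 1.0
    return np.where((lam >= 0.5) & (lam <= 1.5), val, 0.0)


def f_VCE(lambda_f_dot):
    """Active force-velocity factor.

    Zero at or below -10 1/s (shortening faster than the maximum contraction
    velocity), ``-(1/atan 5) atan(-0.5 rate) + 1`` on [-10, 2], constant
    ``pi / (4 atan 5) + 1`` above 2 1/s.  Continuous and non-decreasing.
    """
    rate = np.asarray(lambda_f_dot, dtype=float)
    mid = -np.arctan(-0.5 * rate) / ATAN5 + 1.0
    out = np.where(rate <= -10.0, 0.0, np.where(rate > 2.0, F_VCE_MAX, mid))
    return out


def fiber_nominal_stress(kin: KinPoint, act: ActivationPair, params: MuscleParams):
    """Total nominal fiber stress of the two-population mixture (MPa).

    ``T = T0M [ mu_SO (f_PE + f_LCE f_VCE alpha_SO)
              + mu_FG (f_PE + f_LCE f_VCE alpha_FG) ]``
    """
    return _nominal_stress(
        kin.lambda_f, f_VCE(kin.lambda_f_dot), act, params
    )


def _nominal_stress(lambda_f, f_vce, act: ActivationPair, params: MuscleParams):
    fpe = f_PE(lambda_f, params)
    active = f_LCE(lambda_f) * np.asarray(f_vce) * act.mixed(params)
    return params.t0m * (fpe + active)


# ---------------------------------------------------------------------------
# Strain energy
# ---------------------------------------------------------------------------

def _u_pe(lambda_f, params: MuscleParams):
    # closed-form integral of T0M * f_PE from 1 to lambda_f
    lam = np.asarray(lambda_f, dtype=float)
    val = params.t0m * params.A * (np.exp(params.a * (lam - 1.0) ** 2) - 1.0)
    return np.where(lam > 1.0, val, 0.0)


def muscle_strain_energy(kin: KinPoint, act: ActivationPair, params: MuscleParams):
    """Strain energy density of the muscle (MPa), scalar points only.

    The contractile-element integral over ``lambda_f`` is evaluated by
    adaptive quadrature with the force-velocity factor frozen at the current
    rate (the rate enters parametrically, not variationally).  The passive
    fiber integral is closed-form.  Zero in the reference state.
    """
    J = float(kin.J)
    lam = float(kin.lambda_f)
    u_vol = params.kappa_vol * (J - 1.0)
    u_iso = params.c * (np.exp(params.b * (float(kin.I_tilde_C) - 3.0)) - 1.0)
    u_pe = float(_u_pe(lam, params))
    fv = float(f_VCE(kin.lambda_f_dot))
    g, _ = quad(f_LCE, 1.0, lam)
    u_ce = float(act.mixed(params)) * params.t0m * fv * g
    return u_vol + u_iso + u_pe + u_ce


def muscle_incompressible_energy(
    kin: KinPoint, act: ActivationPair, params: MuscleParams, multiplier: float
):
    """``U + multiplier * W`` with constraint function ``W = J^2 - 1``."""
    return muscle_strain_energy(kin, act, params) + multiplier * (
        float(kin.J) ** 2 - 1.0
    )


# ---------------------------------------------------------------------------
# Second Piola-Kirchhoff stress
# ---------------------------------------------------------------------------

def muscle_pk2_from_C(C, N_m, f_vce, act: ActivationPair, params: MuscleParams,
                      multiplier, element_ids=None):
    """Muscle second Piola-Kirchhoff stress from the right Cauchy-Green tensor.

    ``f_vce`` is the (frozen) force-velocity factor; ``multiplier`` the
    incompressibility Lagrange multiplier.  Batched over leading axes.

    S = kappa J C^-1
        + 2 b c e^{b (I~_C - 3)} (J^(-2/3) I - I~_C/3 C^-1)
        + T (J^(-2/3)/lambda_f N x N - lambda_f/3 C^-1)
        + multiplier 2 J^2 C^-1
    """
    C = np.asarray(C, dtype=float)
    N_m = np.asarray(N_m, dtype=float)
    detC = np.linalg.det(C)
    if np.any(detC <= 0.0):
        bad = np.nonzero(np.atleast_1d(detC) <= 0.0)[0]
        if element_ids is not None:
            bad = np.atleast_1d(np.asarray(element_ids))[bad]
        raise DegenerateElementError(bad)
    J = np.sqrt(detC)
    Cinv = np.linalg.inv(C)
    eye = np.broadcast_to(np.eye(3), C.shape)
    Jm23 = J ** (-2.0 / 3.0)
    trC = np.trace(C, axis1=-2, axis2=-1)
    I_tilde = Jm23 * trC
    NCN = np.einsum("...i,...ij,...j->...", N_m, C, N_m)
    lam_f = np.sqrt(Jm23 * NCN)

    T = _nominal_stress(lam_f, f_vce, act, params)
    NN = N_m[..., :, None] * N_m[..., None, :]

    s = params.kappa_vol * J[..., None, None] * Cinv
    s = s + (2.0 * params.b * params.c * np.exp(params.b * (I_tilde - 3.0)))[
        ..., None, None
    ] * (Jm23[..., None, None] * eye - (I_tilde / 3.0)[..., None, None] * Cinv)
    s = s + T[..., None, None] * (
        (Jm23 / lam_f)[..., None, None] * NN - (lam_f / 3.0)[..., None, None] * Cinv
    )
    s = s + (2.0 * np.asarray(multiplier) * J**2)[..., None, None] * Cinv
    return s


def muscle_second_pk(kin: KinPoint, act: ActivationPair, params: MuscleParams,
                     multiplier):
    """Muscle second Piola-Kirchhoff stress at a kinematic point (MPa).

    The force-velocity factor is evaluated from ``kin.lambda_f_dot`` and held
    frozen (it is not differentiated with respect to strain).
    """
    return muscle_pk2_from_C(
        kin.C, kin.N_m, f_VCE(kin.lambda_f_dot), act, params, multiplier
    )


def stvk_second_pk(E, params: IsotropicElasticParams):
    """Saint Venant-Kirchhoff stress ``S = lambda_m tr(E) I + 2 mu E`` (MPa)."""
    E = np.asarray(E, dtype=float)
    trE = np.trace(E, axis1=-2, axis2=-1)
    eye = np.broadcast_to(np.eye(3), E.shape)
    return params.lame_lambda * trE[..., None, None] * eye + 2.0 * params.lame_mu * E


def stvk_tangent(params: IsotropicElasticParams) -> np.ndarray:
    """Closed-form 6x6 tangent in engineering Voigt order (11,22,33,12,23,13)."""
    lam, mu = params.lame_lambda, params.lame_mu
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] += 2.0 * mu
    D[3, 3] = D[4, 4] = D[5, 5] = mu
    return D


# ---------------------------------------------------------------------------
# Voigt helpers and numerical tangent
# ---------------------------------------------------------------------------

def sym_to_voigt(S) -> np.ndarray:
    """Symmetric tensor components in Voigt order (plain, no shear doubling)."""
    S = np.asarray(S)
    return np.stack([S[..., i, j] for i, j in VOIGT_PAIRS], axis=-1)


def voigt_to_sym(v) -> np.ndarray:
    """Inverse of :func:`sym_to_voigt`."""
    v = np.asarray(v)
    S = np.zeros(v.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(VOIGT_PAIRS):
        S[..., i, j] = v[..., k]
        S[..., j, i] = v[..., k]
    return S


def material_tangent(stress_of_E, E, perturbation: float = 1e-7) -> np.ndarray:
    """Numerical consistent tangent dS/dE as a 6x6 Voigt matrix.

    ``stress_of_E`` maps a symmetric Green-Lagrange tensor to a symmetric
    second Piola-Kirchhoff tensor (any rate factor frozen by the caller).
    Central differences with engineering shear measures: column ``k`` for a
    shear pair (i, j) perturbs ``E_ij`` and ``E_ji`` by h/2 each, so the
    Saint Venant-Kirchhoff tangent reproduces
    ``diag(lambda + 2 mu, ..., mu, ...)`` with ``lambda`` off-diagonals.
    """
    E = np.asarray(E, dtype=float)
    h = perturbation
    D = np.zeros((6, 6))
    for k, (i, j) in enumerate(VOIGT_PAIRS):
        dE = np.zeros((3, 3))
        if i == j:
            dE[i, j] = h
        else:
            dE[i, j] = dE[j, i] = 0.5 * h
        Sp = stress_of_E(E + dE)
        Sm = stress_of_E(E - dE)
        D[:, k] = sym_to_voigt((Sp - Sm) / (2.0 * h))
    return D
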