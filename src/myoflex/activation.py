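"""Activation dynamics: neural excitation to muscle activation level.

Two profile kinds are supported:

* ``ode`` -- first-order rise dynamics driven by a constant neural excitation
  ``u`` with rate constant ``k = u/tau_rise + (1-u)/tau_fall``; the closed-form
  solution from a resting start is ``alpha(t) = alpha_ss (1 - exp(-k t))``
  with steady state
  ``alpha_ss = (u/tau_rise + alpha_min (1-u)/tau_fall) / k``.
* ``linear_ramp`` -- a linear ramp to ``alpha_max`` reached at ``t_peak`` and
  held, used for the contraction-velocity study.

With ``u = 0.5``, ``tau_rise = 0.02 s``, ``tau_fall = 0.2 s`` and
``alpha_min = 0`` the steady state is 10/11 = 0.909..., i.e. the familiar
``alpha_max = 0.91``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivationProfile",
    "activation_rate_constant",
    "steady_state_activation",
    "activation_value",
    "ramp_value",
]


@dataclass(frozen=True)
class ActivationProfile:
    """Parameters of an activation time profile.

    ``kind`` is ``"ode"`` or ``"linear_ramp"``.  ``t_peak`` and ``alpha_max``
    are only meaningful for the ramp kind.
    """

    kind: str = "ode"
    u: float = 0.5
    tau_rise: float = 0.02
    tau_fall: float = 0.2
    alpha_min: float = 0.0
    t_peak: float = 1.0
    alpha_max: float = 0.91

    def __post_init__(self) -> None:
        if self.kind not in ("ode", "linear_ramp"):
            raise ValueError(f"unknown activation profile kind {self.kind!r}")
        if not 0.0 <= self.u <= 0.5:
            raise ValueError("neural excitation u must lie in [0, 0.5]")
        if self.tau_rise <= 0.0 or self.tau_fall <= 0.0:
            raise ValueError("time constants must be > 0")
        if self.t_peak <= 0.0:
            raise ValueError("t_peak must be > 0")
        if not 0.0 < self.alpha_max <= 1.0:
            raise ValueError("alpha_max must lie in (0, 1]")

    def __call__(self, t):
        if self.kind == "ode":
            return activation_value(t, self)
        return ramp_value(t, self)


def activation_rate_constant(u: float, tau_rise: float, tau_fall: float) -> float:
    """Rate constant ``k = u/tau_rise + (1-u)/tau_fall`` (1/s)."""
    return u / tau_rise + (1.0 - u) / tau_fall


def steady_state_activation(
    u: float, tau_rise: float, tau_fall: float, alpha_min: float = 0.0
) -> float:
    """Long-time limit of the activation dynamics."""
    k = activation_rate_constant(u, tau_rise, tau_fall)
    if k == 0.0:
        return alpha_min
    return (u / tau_rise + alpha_min * (1.0 - u) / tau_fall) / k


def activation_value(t, profile: ActivationProfile):
    """Activation level at time ``t`` (s) under first-order dynamics.

    Monotone non-decreasing, bounded by the closed-form steady state.
    Negative times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be non-negative")
    k = activation_rate_constant(profile.u, profile.tau_rise, profile.tau_fall)
    a_ss = steady_state_activation(
        profile.u, profile.tau_rise, profile.tau_fall, profile.alpha_min
    )
    return a_ss * (1.0 - np.exp(-k * t))


def ramp_value(t, profile: ActivationProfile):
    """Linear ramp ``alpha_max * min(t / t_peak, 1)``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be non-negative")
    return profile.alpha_max * np.minimum(t / profile.t_peak, 1.0)
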