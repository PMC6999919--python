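"""Closed-form minimum-time solutions of the linearized (gravity-free) models.

With gravity removed and mass lumped at a point, both tasks reduce to a
double integrator ``I * thetaddot = u`` with a symmetric torque bound
``|u| <= T``. The time-optimal control is bang-bang with a single switch,
and the movement durations have closed forms:

* swing (rest-to-rest move through a total angle dtheta):
  ``t = 2 * sqrt(I * dtheta / T)``
* posture (return to the origin at rest from an initial velocity w0 at
  the origin): ``t = (1 + sqrt(2)) * I * w0 / T``

These closed forms serve as analytic oracles for the nonlinear simulators
(which must agree with them in the zero-gravity limit) and yield the
theoretical scaling predictions under idealized force-scaling regimes.

Also included are the characteristic available-movement times (fall time
and pendulum period) used to normalize response times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "fall_time",
    "pendulum_period",
    "swing_delay_linear",
    "posture_delay_linear",
    "dimensionless_velocity_to_angular",
    "theoretical_exponent",
    "TheoreticalPrediction",
    "POSTURE_SWITCH_FRACTION",
]

#: Fraction of the total gravity-free posture-recovery time at which the
#: torque reverses: (1 + 1/sqrt(2)) / (1 + sqrt(2)) = 1/sqrt(2).
POSTURE_SWITCH_FRACTION = 1.0 / math.sqrt(2.0)


def fall_time(leg_length: float, g: float = 9.81) -> float:
    """Time sqrt(2 L / g) to free-fall through one leg length (s).

    Under geometric similarity (L proportional to M^(1/3)) this scales as
    M^(1/6).
    """
    if leg_length <= 0 or g <= 0:
        raise ValueError("leg length and g must be positive")
    return math.sqrt(2.0 * leg_length / g)


def pendulum_period(leg_length: float, g: float = 9.81) -> float:
    """Small-amplitude period 2 pi sqrt(L / g) of a limb-length pendulum (s)."""
    if leg_length <= 0 or g <= 0:
        raise ValueError("leg length and g must be positive")
    return 2.0 * math.pi * math.sqrt(leg_length / g)


def swing_delay_linear(moi: float, magnitude: float, torque: float) -> float:
    """Minimum rest-to-rest time (s) through total angle ``magnitude`` (rad).

    Bang-bang double integrator: accelerate through half the excursion,
    decelerate through the other half; t = 2 sqrt(I dtheta / T).
    """
    if moi <= 0 or torque <= 0:
        raise ValueError("moment of inertia and torque must be positive")
    if magnitude < 0:
        raise ValueError("movement magnitude cannot be negative")
    return 2.0 * math.sqrt(moi * magnitude / torque)


def posture_delay_linear(moi: float, initial_angular_velocity: float,
                         torque: float) -> float:
    """Minimum time (s) to return to the origin at rest from (0, -w0).

    Bang-bang double integrator with one switch: t = (1 + sqrt(2)) I w0 / T.
    Linear in the perturbation size.
    """
    if moi <= 0 or torque <= 0:
        raise ValueError("moment of inertia and torque must be positive")
    if initial_angular_velocity < 0:
        raise ValueError("velocity magnitude cannot be negative")
    return (1.0 + math.sqrt(2.0)) * moi * initial_angular_velocity / torque


def dimensionless_velocity_to_angular(v_nd: float, limb_length: float,
                                      g: float = 9.81) -> float:
    """Convert a dimensionless (Froude-like) velocity to rad/s.

    The perturbation is specified as v_nd = v / sqrt(g L); the equivalent
    initial angular velocity of the pendulum is v / L = v_nd sqrt(g / L).
    """
    if limb_length <= 0:
        raise ValueError("limb length must be positive")
    if g < 0:
        raise ValueError("g must be non-negative")
    return v_nd * math.sqrt(g / limb_length)


@dataclass(frozen=True)
class TheoreticalPrediction:
    """Predicted scaling exponents of inertial delay under idealized regimes.

    ``delay_exponent`` is the body-mass exponent of absolute inertial delay;
    ``relative_exponent`` is the exponent after normalizing by a
    characteristic movement time (which scales as M^(1/6)), so the two
    always differ by exactly 1/6.
    """

    task: str
    force_scaling: str
    delay_exponent: float
    relative_exponent: float


_THEORY = {
    # (task, force_scaling): delay exponent
    ("swing", "dynamic_similarity"): 1.0 / 6.0,
    ("swing", "cross_sectional_area"): 1.0 / 3.0,
    ("posture", "dynamic_similarity"): 1.0 / 6.0,
    ("posture", "cross_sectional_area"): 1.0 / 2.0,
}


def theoretical_exponent(task: str, force_scaling: str) -> TheoreticalPrediction:
    """Scaling prediction for a task under an idealized force-scaling regime.

    ``force_scaling='dynamic_similarity'`` assumes muscle force grows in
    proportion to body mass; ``'cross_sectional_area'`` assumes it grows as
    M^(2/3). Geometric similarity of lengths and moment arms is assumed in
    both regimes.
    """
    key = (task, force_scaling)
    if key not in _THEORY:
        raise ValueError(
            f"unknown task/force_scaling combination {key!r}; task must be "
            "'swing' or 'posture', force_scaling 'dynamic_similarity' or "
            "'cross_sectional_area'"
        )
    delay = _THEORY[key]
    return TheoreticalPrediction(
        task=task,
        force_scaling=force_scaling,
        delay_exponent=delay,
        relative_exponent=delay - 1.0 / 6.0,
    )
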