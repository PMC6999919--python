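"""Nonlinear swing-task simulation: bang-bang repositioning of a hanging limb.

The forelimb is a distributed-mass pendulum hanging from the shoulder,
with moment of inertia MOI about the pivot, limb mass M_limb, and
center-of-mass distance L_COM. The movement starts from rest at an angle
of -magnitude/2 from the vertical and must end at rest at +magnitude/2
("magnitude" is the total angular excursion). The minimum-time torque
profile under a symmetric bound is bang-bang with a single switch; because
gravity is conservative and the torque work is antisymmetric about the
bottom of the arc, the switch happens exactly when the pendulum passes
through zero angle, and the trajectory is time-symmetric about it. The
simulation applies +T until the zero-angle crossing (detected by the
integrator's event machinery), then -T until the angular velocity crosses
zero; elapsed time is the inertial delay.

Equation of motion, with theta measured from the hanging equilibrium:

    thetaddot = torque / MOI - (M_limb * g * L_COM / MOI) * sin(theta)

The gravity term restores toward the hanging equilibrium. The opposite
(destabilizing) sign can be selected via ``restoring_gravity=False`` for
sensitivity checks, but the restoring sign is the one consistent with a
limb hanging below its pivot and with the reported delay values.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .allometry import ScalingLaw, SwingParameters, swing_parameters
from .linear_models import swing_delay_linear
from .surfaces import DelaySurface, SimulationError, SimulationTrace

__all__ = ["swing_ode", "simulate_swing", "delay_surface_swing"]

#: Default integrator tolerances; tight enough that halving them moves
#: delays by well under 0.01%.
RTOL = 1e-8
ATOL = 1e-10


def swing_ode(state, params: SwingParameters, torque: float,
              restoring_gravity: bool = True):
    """Right-hand side (thetadot, thetaddot) of the swing pendulum."""
    theta, omega = state
    sign = -1.0 if restoring_gravity else 1.0
    grav = sign * params.limb_mass * params.gravity * params.com_length \
        / params.moment_of_inertia
    return omega, torque / params.moment_of_inertia + grav * math.sin(theta)


def _accel(theta: float, params: SwingParameters, torque: float,
           restoring_gravity: bool) -> float:
    return swing_ode((theta, 0.0), params, torque, restoring_gravity)[1]


def simulate_swing(
    params: SwingParameters,
    magnitude: float,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    restoring_gravity: bool = True,
    time_cap_factor: float = 100.0,
) -> SimulationTrace:
    """Simulate one bang-bang swing; ``magnitude`` is the total excursion in degrees.

    Returns the trace with ``inertial_delay`` set to the elapsed time. A
    convergence failure (event not found within ``time_cap_factor`` times
    the gravity-free closed-form estimate) raises SimulationError.
    """
    if magnitude <= 0:
        raise ValueError("movement magnitude must be positive (degrees)")
    mag_rad = math.radians(magnitude)
    theta0 = -0.5 * mag_rad
    torque = params.muscle_torque
    t_lin = swing_delay_linear(params.moment_of_inertia, mag_rad, torque)
    t_cap = time_cap_factor * t_lin

    def rhs_plus(t, y):
        return swing_ode(y, params, +torque, restoring_gravity)

    def rhs_minus(t, y):
        return swing_ode(y, params, -torque, restoring_gravity)

    def theta_zero(t, y):
        return y[0]

    theta_zero.terminal = True
    theta_zero.direction = 1.0

    sol1 = solve_ivp(rhs_plus, (0.0, t_cap), [theta0, 0.0], rtol=rtol, atol=atol,
                     events=theta_zero, dense_output=False)
    if sol1.status != 1 or len(sol1.t_events[0]) == 0:
        raise SimulationError(
            f"swing phase 1 found no zero-angle crossing within {t_cap:.3g} s "
            f"(mass {params.body_mass} kg, magnitude {magnitude} deg, "
            f"solver status {sol1.status})"
        )
    t_switch = sol1.t_events[0][0]
    y_switch = sol1.y_events[0][0]

    def omega_zero(t, y):
        return y[1]

    omega_zero.terminal = True
    omega_zero.direction = -1.0

    sol2 = solve_ivp(rhs_minus, (t_switch, t_switch + t_cap), y_switch,
                     rtol=rtol, atol=atol, events=omega_zero)
    if sol2.status != 1 or len(sol2.t_events[0]) == 0:
        raise SimulationError(
            f"swing phase 2 found no zero-velocity event within cap "
            f"(mass {params.body_mass} kg, magnitude {magnitude} deg)"
        )
    t_end = sol2.t_events[0][0]
    y_end = sol2.y_events[0][0]

    times = np.concatenate([sol1.t, sol2.t[1:], [t_end]])
    angles = np.concatenate([sol1.y[0], sol2.y[0][1:], [y_end[0]]])
    omegas = np.concatenate([sol1.y[1], sol2.y[1][1:], [y_end[1]]])
    torques = np.where(times <= t_switch, +torque, -torque)
    return SimulationTrace(
        times=times,
        angles=angles,
        angular_velocities=omegas,
        torques=torques,
        inertial_delay=float(t_end),
        converged=True,
    )


def delay_surface_swing(
    masses: Sequence[float],
    magnitudes: Sequence[float],
    table: Mapping[str, ScalingLaw] | None = None,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    restoring_gravity: bool = True,
    torque_factor: float = 1.0,
    gravity: float | None = None,
    density: float | None = None,
    isometric_stress: float | None = None,
) -> DelaySurface:
    """Inertial delays for every (mass, magnitude) pair of the swing task.

    ``magnitudes`` are total excursions in degrees. Cells whose simulation
    fails are recorded as NaN with ``converged`` False rather than aborting
    the whole surface.
    """
    masses = np.asarray(masses, dtype=float)
    magnitudes = np.asarray(magnitudes, dtype=float)
    if masses.size == 0 or magnitudes.size == 0:
        raise ValueError("mass and magnitude grids must be non-empty")
    kwargs = {"torque_factor": torque_factor}
    if gravity is not None:
        kwargs["gravity"] = gravity
    if density is not None:
        kwargs["density"] = density
    if isometric_stress is not None:
        kwargs["isometric_stress"] = isometric_stress

    delays = np.full((masses.size, magnitudes.size), np.nan)
    conv = np.zeros_like(delays, dtype=bool)
    for i, m in enumerate(masses):
        params = swing_parameters(m, table, **kwargs)
        for j, mag in enumerate(magnitudes):
            try:
                trace = simulate_swing(params, mag, rtol=rtol, atol=atol,
                                       restoring_gravity=restoring_gravity)
            except SimulationError:
                continue
            delays[i, j] = trace.inertial_delay
            conv[i, j] = True
    return DelaySurface(task="swing", masses=masses, magnitudes=magnitudes,
                        delays=delays, converged=conv,
                        magnitude_name="magnitude_deg")
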