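"""Nonlinear posture-task simulation: inverted-pendulum balance recovery.

The standing animal is a point mass M atop a massless leg of length
L_limb, pivoting about the ground. A forward push gives the pendulum an
initial angular velocity while it is still upright; the ankle extensors of
all four legs (combined torque bound T) must bring it back to upright rest.
Gravity is destabilizing:

    thetaddot = torque / (M L^2) + (g / L) * sin(theta)

with theta measured from vertical. Sign convention: the push is clockwise
(initial angular velocity -w0, w0 > 0), the counter-torque +T acts first,
reversing to -T at a switch time chosen so that the pendulum reaches
theta = 0 exactly as its velocity reaches zero. That single switch time is
the one unknown of a two-point boundary-value problem, solved by shooting:
the position residual at the moment the velocity returns to zero is
monotone in the switch time, so a safeguarded scalar root-finder (Brent)
on a guaranteed bracket converges unconditionally.

Feasibility: with destabilizing gravity there is a largest perturbation
(the capture limit) beyond which no torque profile can stop the fall. The
pendulum escapes once it passes the angle where g-torque exceeds the
muscle torque, M g L sin(theta_c) = T; feasibility of a given push is
decided entirely by the first (braking) arc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .allometry import PostureParameters, ScalingLaw, posture_parameters
from .linear_models import (dimensionless_velocity_to_angular,
                            posture_delay_linear)
from .surfaces import DelaySurface, SimulationError, SimulationTrace

__all__ = [
    "posture_ode",
    "simulate_posture",
    "simulate_posture_angular",
    "max_rejectable_perturbation",
    "delay_surface_posture",
    "PostureSolution",
]

RTOL = 1e-8
ATOL = 1e-10

#: Default absolute tolerance on the terminal boundary conditions
#: (|theta| and |thetadot|), rad and rad/s.
BC_TOL = 1e-6


@dataclass
class PostureSolution:
    """One solved posture recovery: trace, switch time, feasibility."""

    trace: SimulationTrace | None
    switch_time: float
    perturbation_vnd: float
    feasible: bool

    @property
    def inertial_delay(self) -> float:
        if not self.feasible or self.trace is None:
            return math.nan
        return self.trace.inertial_delay


def posture_ode(state, params: PostureParameters, torque: float):
    """Right-hand side (thetadot, thetaddot) of the inverted pendulum."""
    theta, omega = state
    moi = params.moment_of_inertia
    return omega, torque / moi + (params.gravity / params.limb_length) \
        * math.sin(theta)


def _phase_a(params: PostureParameters, w0: float, t_cap: float,
             rtol: float, atol: float):
    """Integrate the braking arc (+T) from (0, -w0).

    Returns (solution, t_peak, t_return) where t_peak is the time the fall
    stops and t_return the time the pendulum is back upright, or None if
    the perturbation is unrecoverable.
    """
    torque = params.muscle_torque

    def rhs(t, y):
        return posture_ode(y, params, +torque)

    def omega_zero(t, y):
        return y[1]

    omega_zero.terminal = False
    omega_zero.direction = 1.0  # velocity rises from -w0 through zero

    def theta_return(t, y):
        return y[0]

    theta_return.terminal = True
    theta_return.direction = 1.0  # back through upright, moving ccw

    def fallen(t, y):
        return y[0] + 0.5 * math.pi

    fallen.terminal = True
    fallen.direction = -1.0

    sol = solve_ivp(rhs, (0.0, t_cap), [0.0, -w0], rtol=rtol, atol=atol,
                    events=(omega_zero, theta_return, fallen),
                    dense_output=True)
    if len(sol.t_events[1]) == 0 or len(sol.t_events[0]) == 0:
        return None  # fell, or never stopped within the cap
    return sol, sol.t_events[0][0], sol.t_events[1][0]


def _second_arc(params: PostureParameters, state, t_cap: float,
                rtol: float, atol: float):
    """Integrate the reversal arc (-T) until the velocity returns to zero.

    Returns (sol, t_end, theta_end); if the stop event never fires (the
    pendulum runs away), t_end is the cap and theta_end the (large) final
    angle, which keeps the shooting residual's sign meaningful.
    """
    torque = params.muscle_torque

    def rhs(t, y):
        return posture_ode(y, params, -torque)

    def omega_zero(t, y):
        return y[1]

    omega_zero.terminal = True
    omega_zero.direction = -1.0

    sol = solve_ivp(rhs, (0.0, t_cap), list(state), rtol=rtol, atol=atol,
                    events=omega_zero)
    if len(sol.t_events[0]):
        return sol, float(sol.t_events[0][0]), float(sol.y_events[0][0][0])
    return sol, float(sol.t[-1]), float(sol.y[0][-1])


def simulate_posture(
    params: PostureParameters,
    v_nd: float,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    bc_tol: float = BC_TOL,
    time_cap_factor: float = 100.0,
) -> PostureSolution:
    """Solve the minimum-time posture recovery for one perturbation size.

    ``v_nd`` is the dimensionless velocity of the push; the initial state is
    (theta=0, thetadot=-v_nd*sqrt(g/L)). Infeasible perturbations (beyond
    the capture limit) return ``feasible=False``; a root-finder failure on
    a feasible problem raises SimulationError.
    """
    if v_nd < 0:
        raise ValueError("perturbation magnitude cannot be negative")
    if v_nd == 0:
        trace = SimulationTrace(times=[0.0], angles=[0.0],
                                angular_velocities=[0.0],
                                torques=[0.0], inertial_delay=0.0)
        return PostureSolution(trace=trace, switch_time=0.0,
                               perturbation_vnd=0.0, feasible=True)
    if params.gravity == 0:
        raise ValueError(
            "simulate_posture requires gravity > 0: the dimensionless "
            "velocity is undefined at g = 0 (use simulate_posture_angular "
            "to pass the initial angular velocity directly)"
        )
    w0 = dimensionless_velocity_to_angular(v_nd, params.limb_length,
                                           params.gravity)
    solution = simulate_posture_angular(params, w0, rtol=rtol, atol=atol,
                                        bc_tol=bc_tol,
                                        time_cap_factor=time_cap_factor)
    solution.perturbation_vnd = v_nd
    return solution


def simulate_posture_angular(
    params: PostureParameters,
    omega0: float,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    bc_tol: float = BC_TOL,
    time_cap_factor: float = 100.0,
) -> PostureSolution:
    """Solve the recovery for a directly specified initial angular velocity.

    ``omega0`` (rad/s, magnitude of the clockwise push) replaces the
    dimensionless parameterization; this entry point also accepts
    ``gravity = 0``, where the problem reduces to the bang-bang double
    integrator and serves as the closed-form cross-check.
    """
    if omega0 < 0:
        raise ValueError("velocity magnitude cannot be negative")
    if omega0 == 0:
        trace = SimulationTrace(times=[0.0], angles=[0.0],
                                angular_velocities=[0.0],
                                torques=[0.0], inertial_delay=0.0)
        return PostureSolution(trace=trace, switch_time=0.0,
                               perturbation_vnd=0.0, feasible=True)
    w0 = omega0
    t_lin = posture_delay_linear(params.moment_of_inertia, w0,
                                 params.muscle_torque)
    t_cap = time_cap_factor * t_lin

    phase_a = _phase_a(params, w0, t_cap, rtol, atol)
    if phase_a is None:
        return PostureSolution(trace=None, switch_time=math.nan,
                               perturbation_vnd=math.nan, feasible=False)
    sol_a, t_peak, t_return = phase_a
    arc2_cap = 20.0 * t_lin + 5.0 * t_return

    def residual(ts: float) -> float:
        theta_s, omega_s = sol_a.sol(ts)
        if omega_s <= 0.0:
            return float(theta_s)  # switching at/before the fall's deepest point
        _, _, theta_end = _second_arc(params, (theta_s, omega_s), arc2_cap,
                                      rtol, atol)
        return theta_end

    r_lo, r_hi = residual(t_peak), residual(t_return)
    if not (r_lo < 0.0 < r_hi):
        raise SimulationError(
            f"posture shooting bracket invalid (residuals {r_lo:.3e}, "
            f"{r_hi:.3e}) at mass {params.body_mass} kg, omega0 {omega0}"
        )
    xtol = max(1e-14, 1e-9 * t_lin)
    t_switch = brentq(residual, t_peak, t_return, xtol=xtol)

    theta_s, omega_s = sol_a.sol(t_switch)
    sol_b, t_b, theta_end = _second_arc(params, (theta_s, omega_s), arc2_cap,
                                        rtol, atol)
    if abs(theta_end) > bc_tol:
        raise SimulationError(
            f"posture boundary condition not met: |theta_end| = "
            f"{abs(theta_end):.3e} rad at mass {params.body_mass} kg, "
            f"omega0 {omega0}"
        )

    torque = params.muscle_torque
    mask = sol_a.t < t_switch
    times = np.concatenate([sol_a.t[mask], [t_switch],
                            t_switch + sol_b.t[1:], [t_switch + t_b]])
    angles = np.concatenate([sol_a.y[0][mask], [theta_s],
                             sol_b.y[0][1:], [theta_end]])
    omegas = np.concatenate([sol_a.y[1][mask], [omega_s],
                             sol_b.y[1][1:], [0.0]])
    torques = np.where(times <= t_switch, +torque, -torque)
    trace = SimulationTrace(times=times, angles=angles,
                            angular_velocities=omegas, torques=torques,
                            inertial_delay=float(t_switch + t_b))
    return PostureSolution(trace=trace, switch_time=float(t_switch),
                           perturbation_vnd=math.nan, feasible=True)


def _is_feasible(params: PostureParameters, v_nd: float, rtol: float,
                 atol: float) -> bool:
    """Cheap feasibility test: does the braking arc stop the fall?"""
    w0 = dimensionless_velocity_to_angular(v_nd, params.limb_length,
                                           params.gravity)
    t_lin = posture_delay_linear(params.moment_of_inertia, w0,
                                 params.muscle_torque)
    return _phase_a(params, w0, 100.0 * t_lin, rtol, atol) is not None


def max_rejectable_perturbation(
    params: PostureParameters,
    *,
    tol: float = 1e-3,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> float:
    """Largest dimensionless velocity from which upright rest is recoverable.

    Bisection on the feasibility of the braking arc, to absolute tolerance
    ``tol``. If the muscle torque exceeds the gravitational torque at every
    angle (T >= M g L), or gravity is off, every perturbation is
    recoverable and ``inf`` is returned.
    """
    if params.gravity == 0:
        return math.inf
    if params.muscle_torque >= params.body_mass * params.gravity \
            * params.limb_length:
        return math.inf

    lo, hi = 0.0, 0.5
    for _ in range(30):
        if not _is_feasible(params, hi, rtol, atol):
            break
        lo, hi = hi, 2.0 * hi
    else:
        return math.inf
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _is_feasible(params, mid, rtol, atol):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def delay_surface_posture(
    masses: Sequence[float],
    v_nd_grid: Sequence[float],
    table: Mapping[str, ScalingLaw] | None = None,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    bc_tol: float = BC_TOL,
    torque_factor: float = 1.0,
    gravity: float | None = None,
    density: float | None = None,
    isometric_stress: float | None = None,
) -> DelaySurface:
    """Inertial delays for every (mass, v_nd) pair of the posture task.

    Infeasible or failed cells are NaN with ``converged`` False.
    """
    masses = np.asarray(masses, dtype=float)
    v_nd_grid = np.asarray(v_nd_grid, dtype=float)
    if masses.size == 0 or v_nd_grid.size == 0:
        raise ValueError("mass and perturbation grids must be non-empty")
    kwargs = {"torque_factor": torque_factor}
    if gravity is not None:
        kwargs["gravity"] = gravity
    if density is not None:
        kwargs["density"] = density
    if isometric_stress is not None:
        kwargs["isometric_stress"] = isometric_stress

    delays = np.full((masses.size, v_nd_grid.size), np.nan)
    conv = np.zeros_like(delays, dtype=bool)
    for i, m in enumerate(masses):
        params = posture_parameters(m, table, **kwargs)
        for j, v in enumerate(v_nd_grid):
            try:
                solution = simulate_posture(params, v, rtol=rtol, atol=atol,
                                            bc_tol=bc_tol)
            except SimulationError:
                continue
            if solution.feasible:
                delays[i, j] = solution.inertial_delay
                conv[i, j] = True
    return DelaySurface(task="posture", masses=masses, magnitudes=v_nd_grid,
                        delays=delays, converged=conv, magnitude_name="vnd")
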