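"""Posture-recovery simulation: shooting solution, feasibility, capture limit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import inertial_delays as idl
from inertial_delays.linear_models import POSTURE_SWITCH_FRACTION
from inertial_delays.posture_sim import posture_ode


@pytest.fixture(scope="module")
def params_1kg():
    return idl.posture_parameters(1.0)


@pytest.fixture(scope="module")
def params_10t():
    return idl.posture_parameters(1e4)


def capture_limit_energy_oracle(params) -> float:
    """Independent closed-form capture limit from an energy balance.

    The pendulum escapes at the angle theta_c where gravity torque equals
    muscle torque, M g L sin(theta_c) = T. The largest recoverable push has
    kinetic energy equal to the net braking work accumulated from upright
    to theta_c: T*theta_c - M g L (1 - cos(theta_c)).
    """
    M, L, T, g = (params.body_mass, params.limb_length, params.muscle_torque,
                  params.gravity)
    mgl = M * g * L
    if T >= mgl:
        return math.inf
    theta_c = math.asin(T / mgl)
    work = T * theta_c - mgl * (1.0 - math.cos(theta_c))
    w_max = math.sqrt(2.0 * work / (M * L ** 2))
    return w_max * math.sqrt(L / g)  # back to dimensionless velocity


class TestPostureOde:
    def test_upright_equilibrium(self, params_1kg):
        assert posture_ode((0.0, 0.0), params_1kg, 0.0) == (0.0, 0.0)

    def test_pure_torque_acceleration(self, params_1kg):
        T = params_1kg.muscle_torque
        _, acc = posture_ode((0.0, 0.0), params_1kg, T)
        assert acc == pytest.approx(T / params_1kg.moment_of_inertia)

    def test_gravity_is_destabilizing(self, params_1kg):
        theta = 1e-3
        _, acc = posture_ode((theta, 0.0), params_1kg, 0.0)
        expected = params_1kg.gravity / params_1kg.limb_length * theta
        assert acc == pytest.approx(expected, rel=1e-6)
        assert acc > 0  # tips further from vertical


class TestSimulatePosture:
    def test_small_perturbation_delay(self, params_1kg):
        sol = idl.simulate_posture(params_1kg, 0.01)
        assert sol.feasible
        assert sol.inertial_delay * 1e3 == pytest.approx(1.5, rel=0.07)

    def test_boundary_conditions_met(self, params_1kg):
        for vnd in (0.01, 0.1, 0.3):
            sol = idl.simulate_posture(params_1kg, vnd)
            assert abs(sol.trace.angles[-1]) < 1e-6
            assert abs(sol.trace.angular_velocities[-1]) < 1e-6

    def test_switch_time_inside_movement(self, params_1kg):
        sol = idl.simulate_posture(params_1kg, 0.2)
        assert 0.0 < sol.switch_time < sol.inertial_delay

    def test_delay_vanishes_with_perturbation(self, params_1kg):
        tiny = idl.simulate_posture(params_1kg, 1e-4)
        assert tiny.inertial_delay < 1e-4
        assert idl.simulate_posture(params_1kg, 0.0).inertial_delay == 0.0

    @settings(max_examples=10)
    @given(mass=st.floats(1e-3, 1e4), w_scale=st.floats(0.1, 3.0))
    def test_gravity_free_limit_matches_closed_form(self, mass, w_scale):
        p = idl.posture_parameters(mass, gravity=0.0)
        w0 = w_scale * p.muscle_torque / p.moment_of_inertia * 0.01
        sol = idl.simulate_posture_angular(p, w0)
        expected = idl.posture_delay_linear(p.moment_of_inertia, w0,
                                            p.muscle_torque)
        assert sol.inertial_delay == pytest.approx(expected, rel=1e-3)
        assert sol.switch_time / sol.inertial_delay == pytest.approx(
            POSTURE_SWITCH_FRACTION, rel=1e-3)

    def test_near_linear_growth_at_small_perturbations(self, params_1kg):
        t1 = idl.simulate_posture(params_1kg, 0.01).inertial_delay
        t2 = idl.simulate_posture(params_1kg, 0.02).inertial_delay
        assert t2 == pytest.approx(2 * t1, rel=5e-3)

    def test_solution_deterministic_and_tolerance_robust(self, params_1kg):
        a = idl.simulate_posture(params_1kg, 0.3)
        b = idl.simulate_posture(params_1kg, 0.3)
        c = idl.simulate_posture(params_1kg, 0.3, rtol=5e-9, atol=5e-11)
        assert a.inertial_delay == b.inertial_delay
        assert c.inertial_delay == pytest.approx(a.inertial_delay, rel=1e-4)

    def test_infeasible_perturbation_flagged(self, params_10t):
        sol = idl.simulate_posture(params_10t, 0.6)  # beyond capture limit
        assert not sol.feasible
        assert math.isnan(sol.inertial_delay)

    def test_rejects_negative_perturbation(self, params_1kg):
        with pytest.raises(ValueError):
            idl.simulate_posture(params_1kg, -0.1)


class TestCaptureLimit:
    def test_ten_ton_limit_near_half(self, params_10t):
        limit = idl.max_rejectable_perturbation(params_10t)
        assert limit == pytest.approx(0.49, abs=0.01)

    def test_matches_energy_oracle(self, params_10t):
        oracle = capture_limit_energy_oracle(params_10t)
        limit = idl.max_rejectable_perturbation(params_10t)
        assert limit == pytest.approx(oracle, abs=2e-3)

    def test_monotone_in_torque(self):
        weak = idl.posture_parameters(1e4, torque_factor=0.5)
        strong = idl.posture_parameters(1e4, torque_factor=2.0)
        assert idl.max_rejectable_perturbation(strong) \
            > idl.max_rejectable_perturbation(weak)

    def test_unbounded_without_gravity(self):
        p = idl.posture_parameters(1e4, gravity=0.0)
        assert idl.max_rejectable_perturbation(p) == math.inf

    def test_unbounded_when_torque_dominates(self):
        # a small animal's combined ankle torque exceeds M g L: any push
        # that leaves the pendulum above the floor is recoverable
        p = idl.posture_parameters(1.0)
        assert p.muscle_torque > p.body_mass * p.gravity * p.limb_length
        assert idl.max_rejectable_perturbation(p) == math.inf


class TestDelaySurfacePosture:
    def test_single_cell_matches_simulate(self, params_1kg):
        surf = idl.delay_surface_posture([1.0], [0.2])
        direct = idl.simulate_posture(params_1kg, 0.2)
        assert surf.delays[0, 0] == pytest.approx(direct.inertial_delay,
                                                  rel=1e-10)

    def test_delays_increase_superlinearly_near_capture(self, posture_surface):
        assert np.all(np.diff(posture_surface.delays, axis=1) > 0)
        # at the largest mass, delay grows faster than linearly in v_nd
        vnd = posture_surface.magnitudes
        d = posture_surface.delays[-1]
        ratio = (d[-1] / d[0]) / (vnd[-1] / vnd[0])
        assert ratio > 1.1

    def test_surface_complete(self, posture_surface):
        assert posture_surface.complete

    def test_infeasible_cells_flagged_not_fatal(self):
        surf = idl.delay_surface_posture([1.0, 1e4], [0.01, 0.6])
        assert surf.converged[0].all()  # 1 kg recovers from anything
        assert not surf.converged[1, 1]  # 10 t cannot reject v_nd = 0.6
        assert np.isnan(surf.delays[1, 1])
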