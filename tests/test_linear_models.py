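"""Closed-form minimum-time solutions versus brute-force integration.

The independent oracle for both closed forms is a time-stepped simulation
of the double integrator under bang-bang torque — no optimal-control
algebra, just stepping and (for the recovery task) bisection on the switch
time.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import inertial_delays as idl
from inertial_delays.linear_models import POSTURE_SWITCH_FRACTION


def brute_force_swing_time(moi, magnitude, torque, n_steps=40_000):
    """Step the double integrator: +T until the midpoint, -T until rest."""
    a = torque / moi
    dt = idl.swing_delay_linear(moi, magnitude, torque) / n_steps * 1.5
    x, v, t = -magnitude / 2.0, 0.0, 0.0
    while x < 0.0:
        v += a * dt
        x += v * dt
        t += dt
    while v > 0.0:
        v -= a * dt
        x += v * dt
        t += dt
    return t


def brute_force_posture_time(moi, w0, torque, n_steps=20_000):
    """Bisection on the switch time of the time-stepped double integrator."""
    a = torque / moi
    t_guess = idl.posture_delay_linear(moi, w0, torque)
    dt = t_guess / n_steps

    def final_position(t_switch):
        x, v, t = 0.0, -w0, 0.0
        while t < t_switch:
            v += a * dt
            x += v * dt
            t += dt
        while v > 0.0 or t <= t_switch + dt:
            v -= a * dt
            x += v * dt
            t += dt
        return x, t

    lo, hi = 0.0, 3.0 * t_guess
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        x_end, _ = final_position(mid)
        if x_end < 0.0:
            lo = mid
        else:
            hi = mid
    return final_position(0.5 * (lo + hi))[1]


class TestCharacteristicTimes:
    def test_fall_time_value(self):
        assert idl.fall_time(0.162, 9.81) == pytest.approx(
            math.sqrt(2 * 0.162 / 9.81))
        assert idl.fall_time(0.162, 9.81) == pytest.approx(0.182, abs=1e-3)

    def test_fall_time_square_root_scaling(self):
        assert idl.fall_time(4 * 0.1) == pytest.approx(2 * idl.fall_time(0.1))

    def test_pendulum_period_values(self):
        assert idl.pendulum_period(9.81, 9.81) == pytest.approx(2 * math.pi)
        assert idl.pendulum_period(0.162, 9.81) == pytest.approx(0.808,
                                                                 abs=1e-3)

    def test_sixth_power_mass_scaling_under_geometric_similarity(self):
        """L propto M^(1/3) makes both characteristic times scale as M^(1/6)."""
        masses = np.geomspace(1e-3, 1e4, 7)
        lengths = 0.162 * masses ** (1.0 / 3.0)
        for fn in (idl.fall_time, idl.pendulum_period):
            times = [fn(L) for L in lengths]
            fit = idl.fit_power_law(masses, times)
            assert fit.exponent == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_domain_errors(self):
        for fn in (idl.fall_time, idl.pendulum_period):
            with pytest.raises(ValueError):
                fn(0.0)
            with pytest.raises(ValueError):
                fn(1.0, 0.0)


class TestSwingClosedForm:
    def test_zero_magnitude_zero_time(self):
        assert idl.swing_delay_linear(1e-3, 0.0, 1.0) == 0.0

    def test_one_kg_one_degree(self):
        t = idl.swing_delay_linear(2.52e-4, math.radians(1.0), 0.545)
        assert t == pytest.approx(5.7e-3, abs=1e-4)

    def test_quadrupling_torque_halves_delay(self):
        t1 = idl.swing_delay_linear(1e-3, 0.5, 1.0)
        t4 = idl.swing_delay_linear(1e-3, 0.5, 4.0)
        assert t4 == pytest.approx(0.5 * t1, rel=1e-12)

    @settings(max_examples=10)
    @given(st.floats(1e-5, 1.0), st.floats(0.01, 2.0), st.floats(0.01, 10.0))
    def test_matches_brute_force(self, moi, magnitude, torque):
        expected = brute_force_swing_time(moi, magnitude, torque)
        assert idl.swing_delay_linear(moi, magnitude, torque) == pytest.approx(
            expected, rel=1e-3)

    @given(st.floats(1e-4, 1.0), st.floats(0.01, 2.0), st.floats(0.01, 10.0),
           st.floats(0.1, 100.0))
    def test_homogeneous_in_inertia_and_torque(self, moi, mag, torque, k):
        assert idl.swing_delay_linear(k * moi, mag, k * torque) \
            == pytest.approx(idl.swing_delay_linear(moi, mag, torque),
                             rel=1e-12)


class TestPostureClosedForm:
    def test_zero_velocity_zero_time(self):
        assert idl.posture_delay_linear(1e-3, 0.0, 1.0) == 0.0

    def test_one_kg_small_perturbation(self):
        moi = 1.0 * 0.162 ** 2
        w0 = idl.dimensionless_velocity_to_angular(0.01, 0.162, 9.81)
        t = idl.posture_delay_linear(moi, w0, 3.41)
        assert t == pytest.approx(1.45e-3, abs=2e-5)

    def test_linear_in_perturbation(self):
        t1 = idl.posture_delay_linear(1e-2, 0.1, 1.0)
        t2 = idl.posture_delay_linear(1e-2, 0.2, 1.0)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    @settings(max_examples=10)
    @given(st.floats(1e-4, 1.0), st.floats(0.01, 5.0), st.floats(0.01, 10.0))
    def test_matches_brute_force_with_bisected_switch(self, moi, w0, torque):
        expected = brute_force_posture_time(moi, w0, torque)
        assert idl.posture_delay_linear(moi, w0, torque) == pytest.approx(
            expected, rel=1e-3)

    def test_switch_fraction_constant(self):
        # (1 + 1/sqrt(2)) / (1 + sqrt(2)) simplifies to 1/sqrt(2)
        assert POSTURE_SWITCH_FRACTION == pytest.approx(
            (1 + 1 / math.sqrt(2)) / (1 + math.sqrt(2)), rel=1e-15)


class TestDimensionlessVelocity:
    def test_zero_maps_to_zero(self):
        assert idl.dimensionless_velocity_to_angular(0.0, 0.3) == 0.0

    def test_reference_value(self):
        w = idl.dimensionless_velocity_to_angular(0.01, 0.162, 9.81)
        assert w == pytest.approx(0.01 * math.sqrt(9.81 / 0.162))
        assert w == pytest.approx(0.0779, abs=1e-4)

    def test_linear_velocity_scales_with_sixth_power(self):
        """v = v_nd*sqrt(gL) fits M^(1/6) under geometric similarity."""
        masses = np.geomspace(1e-3, 1e4, 7)
        lengths = 0.162 * masses ** (1.0 / 3.0)
        v = [idl.dimensionless_velocity_to_angular(0.01, L) * L
             for L in lengths]
        fit = idl.fit_power_law(masses, v)
        assert fit.exponent == pytest.approx(1.0 / 6.0, abs=1e-12)


class TestTheoreticalExponents:
    @pytest.mark.parametrize(
        "task,regime,delay_exp,rel_exp",
        [
            ("swing", "dynamic_similarity", 1 / 6, 0.0),
            ("swing", "cross_sectional_area", 1 / 3, 1 / 6),
            ("posture", "dynamic_similarity", 1 / 6, 0.0),
            ("posture", "cross_sectional_area", 1 / 2, 1 / 3),
        ],
    )
    def test_prediction_table(self, task, regime, delay_exp, rel_exp):
        pred = idl.theoretical_exponent(task, regime)
        assert pred.delay_exponent == pytest.approx(delay_exp, abs=1e-15)
        assert pred.relative_exponent == pytest.approx(rel_exp, abs=1e-15)
        # relative = absolute minus the characteristic-time exponent
        assert pred.delay_exponent - pred.relative_exponent == pytest.approx(
            1 / 6, abs=1e-15)

    def test_unknown_combination_rejected(self):
        with pytest.raises(ValueError):
            idl.theoretical_exponent("swing", "isometry")
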