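"""Scaling-law evaluation, the muscle-torque chain, and parameter tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import inertial_delays as idl
from inertial_delays.allometry import MuscleGroup, mass_grid

TABLE1 = idl.swing_scaling_table()
TABLE2 = idl.posture_scaling_table()


class TestScalingLaw:
    def test_coefficient_is_value_at_one_kg(self):
        assert TABLE1["forelimb_mass"](1.0) == pytest.approx(5.82e-2)
        # M^b = 1 at M = 1 for any law
        for law in {**TABLE1, **TABLE2}.values():
            assert law(1.0) == pytest.approx(law.coefficient)

    def test_direct_exponentiation(self):
        # triceps moment arm at 100 kg: a * 100^0.41
        expected = 8.70e-3 * 100.0 ** 0.41
        assert TABLE1["triceps_moment_arm"](100.0) == pytest.approx(expected)
        assert expected == pytest.approx(5.75e-2, rel=1e-2)

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            TABLE1["forelimb_mass"](0.0)
        with pytest.raises(ValueError):
            TABLE1["forelimb_mass"](-2.0)

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            idl.ScalingLaw(coefficient=-1.0, exponent=0.5)
        with pytest.raises(ValueError):
            idl.ScalingLaw(coefficient=1.0, exponent=0.5,
                           exponent_ci=(0.6, 0.7))

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    def test_multiplicative_property(self, m, k):
        """value(k*M)/value(M) = k^b for every law."""
        law = TABLE1["forelimb_moi"]
        assert law(k * m) / law(m) == pytest.approx(k ** law.exponent,
                                                    rel=1e-12)


class TestMuscleChain:
    def test_triceps_force_at_one_kg(self):
        group = MuscleGroup(TABLE1["triceps_mass"], TABLE1["triceps_length"],
                            TABLE1["triceps_moment_arm"])
        expected = 2e5 * (6.20e-3 / 1060.0) / 1.87e-2  # stress * PCSA
        assert idl.muscle_force(group, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(62.6, rel=1e-2)

    def test_ankle_extensor_force_at_one_kg(self):
        group = MuscleGroup(TABLE2["ankle_extensor_mass"],
                            TABLE2["ankle_extensor_length"],
                            TABLE2["ankle_extensor_moment_arm"])
        expected = 2e5 * (5.10e-3 / 1060.0) / 1.06e-2
        assert idl.muscle_force(group, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(90.8, rel=1e-2)

    def test_force_linear_in_stress(self):
        g1 = MuscleGroup(TABLE1["triceps_mass"], TABLE1["triceps_length"],
                         TABLE1["triceps_moment_arm"], isometric_stress=2e5)
        g2 = MuscleGroup(TABLE1["triceps_mass"], TABLE1["triceps_length"],
                         TABLE1["triceps_moment_arm"], isometric_stress=4e5)
        assert idl.muscle_force(g2, 3.0) == pytest.approx(
            2 * idl.muscle_force(g1, 3.0))

    def test_torques_at_one_kg(self):
        triceps = MuscleGroup(TABLE1["triceps_mass"], TABLE1["triceps_length"],
                              TABLE1["triceps_moment_arm"])
        assert idl.muscle_torque(triceps, 1.0) == pytest.approx(0.545,
                                                                rel=2e-3)
        ankle = MuscleGroup(TABLE2["ankle_extensor_mass"],
                            TABLE2["ankle_extensor_length"],
                            TABLE2["ankle_extensor_moment_arm"],
                            leg_multiplier=4)
        assert idl.muscle_torque(ankle, 1.0) == pytest.approx(3.41, rel=2e-3)

    def test_leg_multiplier_scales_torque(self):
        one = MuscleGroup(TABLE2["ankle_extensor_mass"],
                          TABLE2["ankle_extensor_length"],
                          TABLE2["ankle_extensor_moment_arm"],
                          leg_multiplier=1)
        four = MuscleGroup(TABLE2["ankle_extensor_mass"],
                           TABLE2["ankle_extensor_length"],
                           TABLE2["ankle_extensor_moment_arm"],
                           leg_multiplier=4)
        assert idl.muscle_torque(four, 7.0) == pytest.approx(
            4 * idl.muscle_torque(one, 7.0))

    def test_geometric_similarity_torque_scales_linearly(self):
        """mass law b=1 and length/arm laws b=1/3 give torque exactly M^1."""
        group = MuscleGroup(
            idl.ScalingLaw(1e-2, 1.0), idl.ScalingLaw(2e-2, 1.0 / 3.0),
            idl.ScalingLaw(1e-2, 1.0 / 3.0))
        m = np.geomspace(1e-3, 1e4, 9)
        torques = [idl.muscle_torque(group, x) for x in m]
        fit = idl.fit_power_law(m, torques)
        assert fit.exponent == pytest.approx(1.0, abs=1e-12)


class TestTaskParameters:
    def test_swing_parameters_at_one_kg(self):
        p = idl.swing_parameters(1.0)
        assert p.moment_of_inertia == pytest.approx(2.52e-4)
        assert p.limb_mass == pytest.approx(5.82e-2)
        assert p.com_length == pytest.approx(5.64e-2)
        assert p.gravity == pytest.approx(9.81)

    def test_posture_parameters_at_one_kg(self):
        p = idl.posture_parameters(1.0)
        assert p.limb_length == pytest.approx(0.5 * (1.61e-1 + 1.63e-1))
        assert p.muscle_torque == pytest.approx(3.41, rel=2e-3)
        assert p.body_mass == 1.0

    def test_constructors_are_deterministic(self):
        assert idl.swing_parameters(3.7) == idl.swing_parameters(3.7)
        assert idl.posture_parameters(3.7) == idl.posture_parameters(3.7)


class TestMassGrid:
    def test_default_endpoints_one_gram_to_ten_tons(self):
        grid = mass_grid()
        assert len(grid) == 7
        assert grid[0] == pytest.approx(1e-3)
        assert grid[-1] == pytest.approx(1e4)

    def test_constant_geometric_ratio(self):
        grid = mass_grid()
        ratios = grid[1:] / grid[:-1]
        assert np.allclose(ratios, 10.0 ** (7.0 / 6.0))

    def test_two_point_grid_is_endpoints(self):
        assert mass_grid(2, 1.0, 100.0) == pytest.approx([1.0, 100.0])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            mass_grid(1)
        with pytest.raises(ValueError):
            mass_grid(5, 10.0, 1.0)


def test_parameter_table_roundtrip(tmp_path):
    path = tmp_path / "table.csv"
    idl.write_parameter_table(TABLE1, path)
    back = idl.load_parameter_table(path)
    assert set(back) == set(TABLE1)
    for name in TABLE1:
        assert back[name] == TABLE1[name]
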