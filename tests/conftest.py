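"""Shared fixtures: baseline surfaces and fits, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import inertial_delays as idl

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def masses():
    return idl.mass_grid()


@pytest.fixture(scope="session")
def swing_magnitudes():
    return np.geomspace(1.0, 60.0, 10)


@pytest.fixture(scope="session")
def posture_vnds():
    return np.geomspace(0.01, 0.49, 15)


@pytest.fixture(scope="session")
def swing_surface(masses, swing_magnitudes):
    return idl.delay_surface_swing(masses, swing_magnitudes)


@pytest.fixture(scope="session")
def posture_surface(masses, posture_vnds):
    return idl.delay_surface_posture(masses, posture_vnds)


@pytest.fixture(scope="session")
def swing_fits(swing_surface):
    return idl.fit_delay_scaling(swing_surface)


@pytest.fixture(scope="session")
def posture_fits(posture_surface):
    return idl.fit_delay_scaling(posture_surface)


@pytest.fixture(scope="session")
def smd(swing_fits):
    return idl.build_sensorimotor_model(swing_fits, 30.0)
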