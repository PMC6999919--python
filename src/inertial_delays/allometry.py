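"""Allometric parameterization of the swing and posture tasks.

Body size enters the analysis only through empirical power laws of body
mass, ``value = a * M**b``, fitted in the comparative-morphology literature
for limb inertial properties (forelimb mass, center-of-mass distance,
moment of inertia, limb lengths) and for muscle architecture (muscle mass,
fascicle length, moment arm) of the triceps and ankle-extensor groups.
This module turns a body mass in kilograms into the physical parameters of
the two simulated tasks:

* swing task — a distributed-mass pendulum (the forelimb swinging about
  the shoulder), driven by the shoulder flexor/extensor torque estimated
  from triceps architecture;
* posture task — a point-mass inverted pendulum (the whole body on
  stance limbs), driven by four ankle-extensor groups.

Muscle torque follows the standard physiological chain: muscle volume =
mass / density, PCSA = volume / fascicle length, force = PCSA x isometric
stress, torque = force x moment arm (x number of legs acting).

Units are strict SI throughout (kg, m, s, N, N m, rad). Degrees and
milliseconds appear only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScalingLaw",
    "MuscleGroup",
    "SwingParameters",
    "PostureParameters",
    "evaluate_scaling_law",
    "muscle_force",
    "muscle_torque",
    "swing_parameters",
    "posture_parameters",
    "mass_grid",
    "load_parameter_table",
    "write_parameter_table",
    "swing_scaling_table",
    "posture_scaling_table",
    "MUSCLE_DENSITY",
    "ISOMETRIC_STRESS",
    "GRAVITY",
]

#: Density of mammalian skeletal muscle, kg/m^3.
MUSCLE_DENSITY = 1060.0

#: Isometric force generation capacity of mammalian muscle, N/m^2
#: (20 N/cm^2). Literature values span roughly 7-148 N/cm^2; overridable
#: everywhere it is used.
ISOMETRIC_STRESS = 2.0e5

#: Standard gravity, m/s^2.
GRAVITY = 9.81

_TABLE_COLUMNS = [
    "quantity",
    "unit",
    "coefficient",
    "coef_ci_lo",
    "coef_ci_hi",
    "exponent",
    "exp_ci_lo",
    "exp_ci_hi",
]


@dataclass(frozen=True)
class ScalingLaw:
    """A power law ``value = coefficient * M**exponent`` of body mass.

    The coefficient is the quantity's value at M = 1 kg, in its SI unit;
    the exponent is dimensionless. Optional 95% confidence bounds on both
    carry the uncertainty used by the Monte Carlo stage.
    """

    coefficient: float
    exponent: float
    coefficient_ci: tuple[float, float] | None = None
    exponent_ci: tuple[float, float] | None = None
    quantity_label: str = ""
    unit_label: str = ""

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError(
                f"scaling-law coefficient must be positive, got {self.coefficient!r}"
            )
        if self.coefficient_ci is not None:
            lo, hi = self.coefficient_ci
            if not (lo <= self.coefficient <= hi):
                raise ValueError(
                    f"coefficient {self.coefficient} outside its CI ({lo}, {hi})"
                )
            if not lo > 0:
                raise ValueError("coefficient CI must be strictly positive")
        if self.exponent_ci is not None:
            lo, hi = self.exponent_ci
            if not (lo <= self.exponent <= hi):
                raise ValueError(
                    f"exponent {self.exponent} outside its CI ({lo}, {hi})"
                )

    def __call__(self, mass):
        return evaluate_scaling_law(self, mass)


def evaluate_scaling_law(law: ScalingLaw, mass):
    """Evaluate ``a * mass**b`` for a scalar or array of body masses (kg).

    Raises ValueError for non-positive mass; the laws are fitted on
    log-transformed data and have no meaning at or below zero.
    """
    m = np.asarray(mass, dtype=float)
    if np.any(m <= 0) or not np.all(np.isfinite(m)):
        raise ValueError(f"body mass must be strictly positive, got {mass!r}")
    out = law.coefficient * m ** law.exponent
    return out.item() if np.isscalar(mass) or out.ndim == 0 else out


@dataclass(frozen=True)
class MuscleGroup:
    """Architecture laws and constants for one muscle group.

    ``leg_multiplier`` is the number of legs whose homologous group acts in
    parallel: 1 for the swing task (one forelimb's shoulder actuator), 4
    for the posture task (ankle extensors of all four stance limbs).
    """

    mass_law: ScalingLaw
    length_law: ScalingLaw
    moment_arm_law: ScalingLaw
    density: float = MUSCLE_DENSITY
    isometric_stress: float = ISOMETRIC_STRESS
    leg_multiplier: int = 1

    def __post_init__(self) -> None:
        if self.density <= 0 or self.isometric_stress <= 0:
            raise ValueError("density and isometric stress must be positive")
        if self.leg_multiplier < 1:
            raise ValueError("leg_multiplier must be a positive integer")


def muscle_force(group: MuscleGroup, mass) -> float:
    """Maximum isometric force (N) of one muscle group at a body mass.

    force = stress * PCSA, with PCSA = (muscle mass / density) / length.
    """
    m_musc = evaluate_scaling_law(group.mass_law, mass)
    l_musc = evaluate_scaling_law(group.length_law, mass)
    if np.any(np.asarray(l_musc) <= 0):
        raise ValueError("muscle length must be positive")
    pcsa = (m_musc / group.density) / l_musc
    return group.isometric_stress * pcsa


def muscle_torque(group: MuscleGroup, mass) -> float:
    """Maximum joint torque (N m): force x moment arm x legs acting."""
    force = muscle_force(group, mass)
    arm = evaluate_scaling_law(group.moment_arm_law, mass)
    return force * arm * group.leg_multiplier


@dataclass(frozen=True)
class SwingParameters:
    """Size-specific physical parameters of the swing-task pendulum."""

    body_mass: float  # kg
    limb_mass: float  # kg, forelimb
    com_length: float  # m, pivot to limb center of mass
    moment_of_inertia: float  # kg m^2, forelimb about the shoulder
    muscle_torque: float  # N m, shoulder flexor/extensor bound
    gravity: float = GRAVITY  # m/s^2

    def __post_init__(self) -> None:
        for name in ("body_mass", "limb_mass", "com_length", "moment_of_inertia",
                     "muscle_torque"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gravity < 0:
            raise ValueError("gravity must be non-negative")


@dataclass(frozen=True)
class PostureParameters:
    """Size-specific physical parameters of the posture-task inverted pendulum."""

    body_mass: float  # kg
    limb_length: float  # m, mean of fore- and hindlimb lengths
    muscle_torque: float  # N m, four ankle-extensor groups combined
    gravity: float = GRAVITY  # m/s^2

    def __post_init__(self) -> None:
        for name in ("body_mass", "limb_length", "muscle_torque"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gravity < 0:
            raise ValueError("gravity must be non-negative")

    @property
    def moment_of_inertia(self) -> float:
        """Point-mass inertia M * L^2 about the ground pivot, kg m^2."""
        return self.body_mass * self.limb_length ** 2


# ---------------------------------------------------------------------------
# Parameter tables


def load_parameter_table(path) -> dict[str, ScalingLaw]:
    """Read a CSV of scaling laws into a mapping quantity -> ScalingLaw."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    table: dict[str, ScalingLaw] = {}
    for row in df.itertuples(index=False):
        table[row.quantity] = ScalingLaw(
            coefficient=float(row.coefficient),
            exponent=float(row.exponent),
            coefficient_ci=(float(row.coef_ci_lo), float(row.coef_ci_hi)),
            exponent_ci=(float(row.exp_ci_lo), float(row.exp_ci_hi)),
            quantity_label=str(row.quantity),
            unit_label=str(row.unit),
        )
    return table


def write_parameter_table(table: Mapping[str, ScalingLaw], path) -> None:
    """Write a mapping of scaling laws back to the CSV schema."""
    rows = []
    for name, law in table.items():
        c_lo, c_hi = law.coefficient_ci or (law.coefficient, law.coefficient)
        e_lo, e_hi = law.exponent_ci or (law.exponent, law.exponent)
        rows.append(
            {
                "quantity": name,
                "unit": law.unit_label,
                "coefficient": law.coefficient,
                "coef_ci_lo": c_lo,
                "coef_ci_hi": c_hi,
                "exponent": law.exponent,
                "exp_ci_lo": e_lo,
                "exp_ci_hi": e_hi,
            }
        )
    # 17 significant digits: float64 values survive the round-trip exactly
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, index=False,
                                                      float_format="%.17g")


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def swing_scaling_table() -> dict[str, ScalingLaw]:
    """Packaged swing-task laws: forelimb inertial + triceps architecture."""
    return load_parameter_table(_data_path("swing_task_scaling.csv"))


def posture_scaling_table() -> dict[str, ScalingLaw]:
    """Packaged posture-task laws: limb lengths + ankle-extensor architecture."""
    return load_parameter_table(_data_path("posture_task_scaling.csv"))


# ---------------------------------------------------------------------------
# Task parameter constructors


def _triceps_group(table, density, stress) -> MuscleGroup:
    return MuscleGroup(
        mass_law=table["triceps_mass"],
        length_law=table["triceps_length"],
        moment_arm_law=table["triceps_moment_arm"],
        density=density,
        isometric_stress=stress,
        leg_multiplier=1,
    )


def _ankle_extensor_group(table, density, stress, leg_multiplier=4) -> MuscleGroup:
    return MuscleGroup(
        mass_law=table["ankle_extensor_mass"],
        length_law=table["ankle_extensor_length"],
        moment_arm_law=table["ankle_extensor_moment_arm"],
        density=density,
        isometric_stress=stress,
        leg_multiplier=leg_multiplier,
    )


def swing_parameters(
    mass: float,
    table: Mapping[str, ScalingLaw] | None = None,
    *,
    density: float = MUSCLE_DENSITY,
    isometric_stress: float = ISOMETRIC_STRESS,
    gravity: float = GRAVITY,
    torque_factor: float = 1.0,
) -> SwingParameters:
    """Build swing-task parameters for one body mass (kg).

    Limb fields come from the forelimb inertial-property laws; the torque
    bound from the triceps chain (the shoulder antagonists are assumed to
    scale identically, so one symmetric bound applies in both directions).
    ``torque_factor`` scales the torque bound for sensitivity analyses.
    """
    if table is None:
        table = swing_scaling_table()
    group = _triceps_group(table, density, isometric_stress)
    return SwingParameters(
        body_mass=float(mass),
        limb_mass=evaluate_scaling_law(table["forelimb_mass"], mass),
        com_length=evaluate_scaling_law(table["forelimb_com_length"], mass),
        moment_of_inertia=evaluate_scaling_law(table["forelimb_moi"], mass),
        muscle_torque=muscle_torque(group, mass) * torque_factor,
        gravity=gravity,
    )


def posture_parameters(
    mass: float,
    table: Mapping[str, ScalingLaw] | None = None,
    *,
    density: float = MUSCLE_DENSITY,
    isometric_stress: float = ISOMETRIC_STRESS,
    gravity: float = GRAVITY,
    leg_multiplier: int = 4,
    torque_factor: float = 1.0,
) -> PostureParameters:
    """Build posture-task parameters for one body mass (kg).

    Pendulum length is the mean of the forelimb and hindlimb length laws
    (the point mass stands for the whole-body center of mass); torque is
    ``leg_multiplier`` times one ankle-extensor group.
    """
    if table is None:
        table = posture_scaling_table()
    group = _ankle_extensor_group(table, density, isometric_stress, leg_multiplier)
    limb_length = 0.5 * (
        evaluate_scaling_law(table["forelimb_length"], mass)
        + evaluate_scaling_law(table["hindlimb_length"], mass)
    )
    return PostureParameters(
        body_mass=float(mass),
        limb_length=limb_length,
        muscle_torque=muscle_torque(group, mass) * torque_factor,
        gravity=gravity,
    )


def mass_grid(n: int = 7, m_min: float = 1e-3, m_max: float = 1e4) -> np.ndarray:
    """Geometrically spaced body masses, endpoints inclusive.

    Defaults span the terrestrial-mammal size range: seven masses from one
    gram to ten metric tons.
    """
    if n < 2:
        raise ValueError("mass grid needs at least two points")
    if not (0 < m_min < m_max):
        raise ValueError("require 0 < m_min < m_max")
    return np.geomspace(m_min, m_max, n)
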