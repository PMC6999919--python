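"""Response times: inertial plus sensorimotor delays, and their budgets.

Sensorimotor delay (the summed neural and muscular latencies before a
corrective movement begins) scales across terrestrial mammals as M^0.21.
Only the exponent is carried over from the literature; the coefficient is
anchored by the convention that in a one-kilogram animal the sensorimotor
delay equals the swing-task inertial delay of a 30-degree movement
(approximately 31 ms). With both delay families expressed as power laws,
three derived quantities follow:

* crossover magnitude — the movement size at which inertial delay first
  equals sensorimotor delay for a given body mass; itself a power law of
  mass with a negative exponent (bigger animals cross over at smaller
  movements);
* response time — sensorimotor plus inertial delay;
* relative response time — response time divided by an available-movement
  -time law. The default normalization is anchored to the sprint swing
  duration of a 1 kg animal (148 ms) and uses the characteristic-time
  exponent 1/6 from the pendulum/fall-time analysis, which is the scaling
  the normalized results are expressed against; the empirical sprint-swing
  law 148 * M**0.13 ms is available as ``available_movement_time`` and as
  an override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allometry import ScalingLaw, posture_scaling_table
from .linear_models import fall_time, pendulum_period
from .powerlaw_fit import (PowerLawFit, average_exponent,
                           fit_coefficient_magnitude_law, fit_delay_scaling,
                           fit_power_law)
from . import swing_sim, posture_sim

__all__ = [
    "SensorimotorDelayModel",
    "CrossoverLaw",
    "DelayScalingModel",
    "build_sensorimotor_model",
    "crossover_magnitude",
    "fit_crossover_law",
    "available_movement_time",
    "relative_response_time",
    "fit_relative_response_law",
    "torque_sensitivity",
    "CrossoverOutOfRange",
]

#: Literature body-mass exponent of sensorimotor delay.
SMD_EXPONENT = 0.21

#: Sprint swing duration at 1 kg (s) and its empirical mass exponent.
SPRINT_SWING_COEF = 0.148
SPRINT_SWING_EXPONENT = 0.13

#: Characteristic-movement-time exponent (fall time, pendulum period under
#: geometric similarity); default normalization for relative response time.
CHARACTERISTIC_EXPONENT = 1.0 / 6.0


class CrossoverOutOfRange(ValueError):
    """Crossover magnitude falls outside the simulated magnitude range."""


@dataclass(frozen=True)
class DelayScalingModel:
    """Separable power-law model of inertial delay, delay = k * mag^p * M^e.

    Built from the per-magnitude fits of a delay surface: ``k`` and ``p``
    from the coefficient-versus-magnitude law, ``e`` as the average
    exponent across magnitudes. ``mag`` is degrees for the swing task and
    dimensionless velocity for the posture task.
    """

    task: str
    k: float
    p: float
    e: float
    magnitude_range: tuple[float, float]

    @classmethod
    def from_fits(cls, task: str, fits: Sequence[PowerLawFit]) -> "DelayScalingModel":
        claw = fit_coefficient_magnitude_law(fits)
        mags = [f.magnitude for f in fits]
        return cls(task=task, k=claw.coefficient, p=claw.exponent,
                   e=average_exponent(fits),
                   magnitude_range=(min(mags), max(mags)))

    def delay(self, mass: float, magnitude: float) -> float:
        return self.k * magnitude ** self.p * mass ** self.e


@dataclass(frozen=True)
class SensorimotorDelayModel:
    """Power law of sensorimotor delay versus body mass (seconds, kg)."""

    coefficient: float  # s at 1 kg
    exponent: float = SMD_EXPONENT
    anchor: str = ""

    def delay(self, mass):
        m = np.asarray(mass, dtype=float)
        out = self.coefficient * m ** self.exponent
        return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class CrossoverLaw:
    """Crossover magnitude versus body mass, magnitude = a * M^b."""

    task: str
    coefficient: float  # degrees (swing) or dimensionless velocity (posture)
    exponent: float

    def __call__(self, mass):
        m = np.asarray(mass, dtype=float)
        out = self.coefficient * m ** self.exponent
        return out.item() if out.ndim == 0 else out


def build_sensorimotor_model(
    fits: Sequence[PowerLawFit],
    anchor_magnitude: float = 30.0,
    *,
    task: str = "swing",
    exponent: float = SMD_EXPONENT,
    coefficient_override: float | None = None,
) -> SensorimotorDelayModel:
    """Anchor the sensorimotor-delay law to the inertial delay at 1 kg.

    The coefficient is the fitted inertial delay of a 1 kg animal at
    ``anchor_magnitude`` (30 degrees for the swing task by convention),
    evaluated from the coefficient-versus-magnitude law so the crossover
    construction is exactly self-consistent at the anchor.
    """
    if coefficient_override is not None:
        return SensorimotorDelayModel(
            coefficient=coefficient_override, exponent=exponent,
            anchor="coefficient override")
    model = DelayScalingModel.from_fits(task, fits)
    lo, hi = model.magnitude_range
    if not (lo <= anchor_magnitude <= hi):
        raise ValueError(
            f"anchor magnitude {anchor_magnitude} outside fitted range "
            f"({lo}, {hi})"
        )
    return SensorimotorDelayModel(
        coefficient=model.delay(1.0, anchor_magnitude),
        exponent=exponent,
        anchor=(f"equal to {task} inertial delay of a {anchor_magnitude}"
                " magnitude movement at 1 kg"),
    )


def crossover_magnitude(
    task: str,
    mass: float,
    smd: SensorimotorDelayModel,
    fits: Sequence[PowerLawFit],
    *,
    extrapolate: bool = False,
) -> float:
    """Movement magnitude at which inertial delay equals sensorimotor delay.

    Solves ``k * mag^p * M^e = smd(M)`` for mag using the separable
    power-law model of the fitted surface; the model is monotone in mag, so
    the root is unique and solved exactly in log space. Crossovers outside
    the simulated magnitude range raise CrossoverOutOfRange unless
    ``extrapolate=True``.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    model = DelayScalingModel.from_fits(task, fits)
    target = smd.delay(mass)
    log_mag = (math.log(target) - math.log(model.k)
               - model.e * math.log(mass)) / model.p
    mag = math.exp(log_mag)
    lo, hi = model.magnitude_range
    if not (lo <= mag <= hi) and not extrapolate:
        raise CrossoverOutOfRange(
            f"crossover magnitude {mag:.4g} for {mass} kg lies outside the "
            f"simulated range ({lo}, {hi}); pass extrapolate=True to "
            "extend the fitted power law"
        )
    return mag


def fit_crossover_law(
    task: str,
    smd: SensorimotorDelayModel,
    fits: Sequence[PowerLawFit],
    masses: Sequence[float],
) -> CrossoverLaw:
    """Power law of the crossover magnitude across the mass grid.

    Extrapolates the fitted delay model where the crossover exceeds the
    simulated magnitude range (it does at the extreme ends of the mammalian
    size range).
    """
    mags = [crossover_magnitude(task, m, smd, fits, extrapolate=True)
            for m in masses]
    fit = fit_power_law(np.asarray(masses, dtype=float), mags)
    return CrossoverLaw(task=task, coefficient=fit.coefficient,
                        exponent=fit.exponent)


def available_movement_time(
    mass: float,
    kind: str,
    table: Mapping[str, ScalingLaw] | None = None,
    *,
    gravity: float = 9.81,
) -> float:
    """Task-relevant time budget (s) for one body mass.

    ``sprint_swing`` is the empirical swing duration at maximum sprint
    speed, 0.148 * M**0.13 s; ``fall`` and ``pendulum_period`` are the
    characteristic times of a body falling through, or swinging at, the
    mean limb length of the posture table.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if kind == "sprint_swing":
        return SPRINT_SWING_COEF * mass ** SPRINT_SWING_EXPONENT
    if kind in ("fall", "pendulum_period"):
        if table is None:
            table = posture_scaling_table()
        length = 0.5 * (table["forelimb_length"](mass)
                        + table["hindlimb_length"](mass))
        fn = fall_time if kind == "fall" else pendulum_period
        return fn(length, gravity)
    raise ValueError(f"unknown movement-time kind {kind!r}")


def _available_law(coefficient: float | None, exponent: float | None):
    c = SPRINT_SWING_COEF if coefficient is None else coefficient
    e = CHARACTERISTIC_EXPONENT if exponent is None else exponent
    return c, e


def relative_response_time(
    mass: float,
    magnitude: float,
    smd: SensorimotorDelayModel,
    fits: Sequence[PowerLawFit],
    *,
    task: str = "swing",
    available_coefficient: float | None = None,
    available_exponent: float | None = None,
) -> float:
    """Response time as a fraction of the available movement time.

    Numerator: sensorimotor delay plus the fitted inertial delay of a
    ``magnitude`` movement at ``mass``. Denominator: the available-time
    power law (defaults: 0.148 s at 1 kg, exponent 1/6).
    """
    model = DelayScalingModel.from_fits(task, fits)
    c, e = _available_law(available_coefficient, available_exponent)
    response = smd.delay(mass) + model.delay(mass, magnitude)
    return response / (c * mass ** e)


def fit_relative_response_law(
    masses: Sequence[float],
    magnitude: float,
    smd: SensorimotorDelayModel,
    fits: Sequence[PowerLawFit],
    *,
    task: str = "swing",
    available_coefficient: float | None = None,
    available_exponent: float | None = None,
) -> PowerLawFit:
    """Power law of relative response time across the mass grid."""
    values = [relative_response_time(m, magnitude, smd, fits, task=task,
                                     available_coefficient=available_coefficient,
                                     available_exponent=available_exponent)
              for m in masses]
    return fit_power_law(np.asarray(masses, dtype=float), values)


def torque_sensitivity(
    task: str,
    factors: Sequence[float],
    masses: Sequence[float],
    magnitudes: Sequence[float],
    table: Mapping[str, ScalingLaw] | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Average scaling exponent when muscle torque is scaled by each factor.

    Reruns the delay surface and per-magnitude fits with the torque bound
    multiplied by every entry of ``factors``; quantifies how robust the
    scaling exponent is to misestimated muscle strength.
    """
    if np.any(np.asarray(factors, dtype=float) <= 0):
        raise ValueError("torque factors must be positive")
    rows = []
    for factor in factors:
        if task == "swing":
            surf = swing_sim.delay_surface_swing(
                masses, magnitudes, table, rtol=rtol, atol=atol,
                torque_factor=float(factor))
        elif task == "posture":
            surf = posture_sim.delay_surface_posture(
                masses, magnitudes, table, rtol=rtol, atol=atol,
                torque_factor=float(factor))
        else:
            raise ValueError(f"unknown task {task!r}")
        rows.append({"factor": float(factor),
                     "average_exponent": average_exponent(
                         fit_delay_scaling(surf))})
    return pd.DataFrame(rows)
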