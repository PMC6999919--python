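"""Run configuration: one serializable object that defines a full analysis.

Defaults reproduce the baseline analysis: seven masses from one gram to
ten metric tons, swing magnitudes 1-60 degrees (10 log-spaced levels),
posture perturbations 0.01-0.49 dimensionless velocity (15 log-spaced
levels), standard muscle constants, and the anchored sensorimotor-delay
law. A run's config is written alongside its outputs so every artifact is
traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

__all__ = ["AnalysisConfig"]


def _default_swing_magnitudes() -> list[float]:
    return [float(x) for x in np.geomspace(1.0, 60.0, 10)]


def _default_posture_vnd() -> list[float]:
    return [float(x) for x in np.geomspace(0.01, 0.49, 15)]


@dataclass
class AnalysisConfig:
    # mass grid
    mass_n: int = 7
    mass_min_kg: float = 1e-3
    mass_max_kg: float = 1e4
    # movement-magnitude grids
    swing_magnitudes_deg: list[float] = field(
        default_factory=_default_swing_magnitudes)
    posture_vnd: list[float] = field(default_factory=_default_posture_vnd)
    # physical constants
    gravity: float = 9.81
    muscle_density: float = 1060.0
    isometric_stress: float = 2.0e5  # N/m^2 (20 N/cm^2)
    # integrator
    rtol: float = 1e-8
    atol: float = 1e-10
    # Monte Carlo
    mc_draws: int = 500
    mc_seed: int = 12345
    mc_df: int = 20
    mc_swing_magnitude_deg: float = 60.0
    mc_posture_vnd: float = 0.10
    # sensorimotor delay
    smd_exponent: float = 0.21
    smd_anchor_deg: float = 30.0
    smd_coefficient_s: float | None = None  # override; None anchors at 1 kg
    # relative-response normalization (available movement time)
    available_coefficient_s: float = 0.148
    available_exponent: float = 1.0 / 6.0
    # torque sensitivity factors
    torque_factors: list[float] = field(default_factory=lambda: [0.5, 1.0, 4.0])

    def masses(self) -> np.ndarray:
        return np.geomspace(self.mass_min_kg, self.mass_max_kg, self.mass_n)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    def hash(self) -> str:
        """Stable content hash of the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
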