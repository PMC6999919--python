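"""Shared result containers: simulation traces and delay surfaces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationTrace", "DelaySurface", "SimulationError"]


class SimulationError(RuntimeError):
    """Raised when an integration or root-finding step fails to converge."""


@dataclass
class SimulationTrace:
    """Time series of one bang-bang simulation.

    ``torques`` holds the applied torque at each sample (piecewise +/-T);
    ``inertial_delay`` equals the final time stamp, the minimum movement
    time for the task instance.
    """

    times: np.ndarray
    angles: np.ndarray
    angular_velocities: np.ndarray
    torques: np.ndarray
    inertial_delay: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.angular_velocities = np.asarray(self.angular_velocities, dtype=float)
        self.torques = np.asarray(self.torques, dtype=float)
        n = len(self.times)
        if not (len(self.angles) == len(self.angular_velocities)
                == len(self.torques) == n):
            raise ValueError("trace arrays must have equal length")
        if n and np.any(np.diff(self.times) < 0):
            raise ValueError("trace times must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "angle_rad": self.angles,
                "angular_velocity_rad_s": self.angular_velocities,
                "torque_Nm": self.torques,
            }
        )


@dataclass
class DelaySurface:
    """Inertial delays on a (mass grid x movement-magnitude grid) lattice.

    ``delays`` has shape (n_masses, n_magnitudes), in seconds; cells whose
    simulation failed or was infeasible are NaN with ``converged`` False.
    ``magnitude_name`` labels the second axis: ``magnitude_deg`` for the
    swing task, ``vnd`` for the posture task.
    """

    task: str
    masses: np.ndarray
    magnitudes: np.ndarray
    delays: np.ndarray
    converged: np.ndarray = field(default=None)  # type: ignore[assignment]
    magnitude_name: str = "magnitude_deg"

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        if self.delays.shape != (len(self.masses), len(self.magnitudes)):
            raise ValueError("delays must have shape (n_masses, n_magnitudes)")
        if self.converged is None:
            self.converged = np.isfinite(self.delays)
        self.converged = np.asarray(self.converged, dtype=bool)
        if self.converged.shape != self.delays.shape:
            raise ValueError("converged mask must match delays shape")

    @property
    def complete(self) -> bool:
        return bool(self.converged.all())

    def column(self, magnitude: float) -> np.ndarray:
        """Delays across masses at one magnitude level (must be on the grid)."""
        j = np.flatnonzero(np.isclose(self.magnitudes, magnitude))
        if len(j) != 1:
            raise KeyError(f"magnitude {magnitude} not on the surface grid")
        return self.delays[:, j[0]]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: mass_kg, <magnitude_name>, delay_s, converged."""
        mm, gg = np.meshgrid(self.masses, self.magnitudes, indexing="ij")
        return pd.DataFrame(
            {
                "mass_kg": mm.ravel(),
                self.magnitude_name: gg.ravel(),
                "delay_s": self.delays.ravel(),
                "converged": self.converged.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, task: str | None = None) -> "DelaySurface":
        df = pd.read_csv(path)
        mag_name = "magnitude_deg" if "magnitude_deg" in df.columns else "vnd"
        masses = np.unique(df["mass_kg"].to_numpy())
        mags = np.unique(df[mag_name].to_numpy())
        delays = np.full((len(masses), len(mags)), np.nan)
        conv = np.zeros_like(delays, dtype=bool)
        i = np.searchsorted(masses, df["mass_kg"].to_numpy())
        j = np.searchsorted(mags, df[mag_name].to_numpy())
        delays[i, j] = df["delay_s"].to_numpy()
        conv[i, j] = df["converged"].to_numpy(dtype=bool)
        if task is None:
            task = "swing" if mag_name == "magnitude_deg" else "posture"
        return cls(task=task, masses=masses, magnitudes=mags, delays=delays,
                   converged=conv, magnitude_name=mag_name)
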