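"""Power-law extraction from delay surfaces by log-log least squares.

Inertial delays are summarized, per movement magnitude, as a power law of
body mass: log10(delay) is regressed on log10(mass) by ordinary least
squares; the intercept back-transforms to the coefficient (the 1-kg delay)
and the slope is the scaling exponent. The headline result of each task is
the unweighted mean exponent across magnitude levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .surfaces import DelaySurface

__all__ = [
    "PowerLawFit",
    "fit_power_law",
    "fit_delay_scaling",
    "average_exponent",
    "fit_coefficient_magnitude_law",
    "fits_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of ``value = coefficient * mass**exponent`` on log10 scales.

    ``residuals`` are per-point log10-space residuals (observed - fitted);
    ``magnitude`` tags the movement-magnitude level the fit belongs to when
    it comes from a delay surface.
    """

    coefficient: float
    exponent: float
    r_squared: float
    n_points: int
    residuals: np.ndarray
    coefficient_se_log10: float = np.nan
    exponent_se: float = np.nan
    magnitude: float | None = None

    def predict(self, mass):
        m = np.asarray(mass, dtype=float)
        out = self.coefficient * m ** self.exponent
        return out.item() if out.ndim == 0 else out


def fit_power_law(masses: Sequence[float], values: Sequence[float],
                  magnitude: float | None = None) -> PowerLawFit:
    """Fit a power law to (mass, value) pairs; all values must be positive."""
    x = np.asarray(masses, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("masses and values must be 1-d of equal length")
    if len(x) < 2:
        raise ValueError("power-law fit needs at least two points")
    if np.any(x <= 0):
        raise ValueError("masses must be strictly positive")
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError("values must be strictly positive and finite")
    lx, ly = np.log10(x), np.log10(y)
    res = stats.linregress(lx, ly)
    fitted = res.intercept + res.slope * lx
    return PowerLawFit(
        coefficient=float(10.0 ** res.intercept),
        exponent=float(res.slope),
        r_squared=float(res.rvalue ** 2),
        n_points=len(x),
        residuals=ly - fitted,
        coefficient_se_log10=float(res.intercept_stderr),
        exponent_se=float(res.stderr),
        magnitude=magnitude,
    )


def fit_delay_scaling(surface: DelaySurface) -> list[PowerLawFit]:
    """One power-law fit per magnitude level, across the mass grid.

    Magnitude levels with any unconverged cell are skipped with a log
    notice; the returned fits carry their magnitude tags.
    """
    fits: list[PowerLawFit] = []
    for j, mag in enumerate(surface.magnitudes):
        ok = surface.converged[:, j]
        if not ok.all():
            log.warning(
                "skipping %s level %s=%g: %d/%d cells unconverged",
                surface.task, surface.magnitude_name, mag,
                int((~ok).sum()), len(ok),
            )
            continue
        fits.append(fit_power_law(surface.masses, surface.delays[:, j],
                                  magnitude=float(mag)))
    return fits


def average_exponent(fits: Sequence[PowerLawFit]) -> float:
    """Unweighted mean scaling exponent across magnitude levels."""
    if len(fits) == 0:
        raise ValueError("no fits to average")
    return float(np.mean([f.exponent for f in fits]))


def fit_coefficient_magnitude_law(fits: Sequence[PowerLawFit]) -> PowerLawFit:
    """Power law of the fitted 1-kg coefficients versus movement magnitude.

    For the swing task the coefficient grows as the square root of the
    excursion; for the posture task nearly linearly in the dimensionless
    velocity. The fit quantifies that dependence.
    """
    if len(fits) < 2:
        raise ValueError("need fits at two or more magnitude levels")
    mags = [f.magnitude for f in fits]
    if any(m is None for m in mags):
        raise ValueError("fits must carry magnitude tags")
    return fit_power_law(np.asarray(mags, dtype=float),
                         [f.coefficient for f in fits])


def fits_to_frame(fits: Sequence[PowerLawFit],
                  magnitude_name: str = "magnitude") -> pd.DataFrame:
    """Tabulate per-magnitude fits for CSV export."""
    return pd.DataFrame(
        {
            magnitude_name: [f.magnitude for f in fits],
            "coefficient_s": [f.coefficient for f in fits],
            "exponent": [f.exponent for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "n_points": [f.n_points for f in fits],
        }
    )
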