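"""Monte Carlo propagation of scaling-law uncertainty to delay power laws.

Each input scaling law carries 95% confidence intervals on its coefficient
and exponent. A draw replaces every law by a random variate: the exponent
from a t-location-scale distribution centered on the printed value with
scale = CI half-width / t-critical, and the coefficient the same way on
the log10 scale (which preserves positivity and matches the log-space
regression the CIs came from). Coefficients and exponents are drawn
independently within and across laws — the within-regression correlation
between a and b is not recoverable from printed intervals, which makes
these intervals somewhat conservative.

For every draw the task parameters are rebuilt, the delay surface is
re-simulated over the mass grid, and the power law refit; 95% confidence
intervals are the baseline point estimate +/- 1.96 times the standard
deviation of the sampled coefficient/exponent distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import ScalingLaw
from .powerlaw_fit import fit_delay_scaling
from .surfaces import SimulationError
from . import swing_sim, posture_sim

__all__ = ["MonteCarloSummary", "sample_scaling_laws", "propagate",
           "summaries_to_frame"]

#: Default degrees of freedom for the t-distributions built from printed
#: CIs (the source studies' sample sizes are not printed).
DEFAULT_DF = 20


@dataclass
class MonteCarloSummary:
    """Sampled distribution of one magnitude level's fitted power law."""

    task: str
    magnitude: float
    n_draws: int
    coefficient_samples: np.ndarray
    exponent_samples: np.ndarray
    coefficient_point: float
    exponent_point: float
    coefficient_ci: tuple[float, float]
    exponent_ci: tuple[float, float]
    seed: int
    n_failures: int = 0


def _t_scale(ci: tuple[float, float], center: float, tcrit: float) -> float:
    lo, hi = ci
    return 0.5 * (hi - lo) / tcrit if hi > lo else 0.0


def sample_scaling_laws(
    laws: Mapping[str, ScalingLaw],
    rng: np.random.Generator,
    df: int = DEFAULT_DF,
) -> dict[str, ScalingLaw]:
    """One random draw of every law in a parameter table.

    Every law must carry both CIs. Zero-width CIs degenerate to the mean.
    """
    tcrit = stats.t.ppf(0.975, df)
    out: dict[str, ScalingLaw] = {}
    for name, law in laws.items():
        if law.coefficient_ci is None or law.exponent_ci is None:
            raise ValueError(f"law {name!r} is missing confidence intervals")
        log_a = np.log10(law.coefficient)
        log_ci = tuple(np.log10(law.coefficient_ci))
        a_scale = _t_scale(log_ci, log_a, tcrit)
        b_scale = _t_scale(law.exponent_ci, law.exponent, tcrit)
        a = 10.0 ** (log_a + a_scale * stats.t.rvs(df, random_state=rng)) \
            if a_scale else law.coefficient
        b = law.exponent + b_scale * stats.t.rvs(df, random_state=rng) \
            if b_scale else law.exponent
        out[name] = ScalingLaw(coefficient=float(a), exponent=float(b),
                               quantity_label=law.quantity_label,
                               unit_label=law.unit_label)
    return out


def _surface(task: str, masses, magnitudes, table, rtol, atol):
    if task == "swing":
        return swing_sim.delay_surface_swing(masses, magnitudes, table,
                                             rtol=rtol, atol=atol)
    if task == "posture":
        return posture_sim.delay_surface_posture(masses, magnitudes, table,
                                                 rtol=rtol, atol=atol)
    raise ValueError(f"unknown task {task!r}")


def propagate(
    task: str,
    magnitudes: Sequence[float],
    n_draws: int,
    seed: int,
    table: Mapping[str, ScalingLaw],
    masses: Sequence[float],
    *,
    df: int = DEFAULT_DF,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_failure_fraction: float = 0.01,
) -> list[MonteCarloSummary]:
    """Monte Carlo confidence intervals for the fitted delay power laws.

    Runs ``n_draws`` re-simulations of the chosen task over ``masses`` at
    each magnitude level, each with a fresh draw of the scaling laws, and
    summarizes the resulting coefficient/exponent distributions. Draws in
    which any cell fails (e.g. a sampled parameter set makes a perturbation
    unrecoverable) are discarded; more than ``max_failure_fraction`` of
    failed draws aborts with an error.
    """
    if n_draws < 2:
        raise ValueError("need at least two draws")
    magnitudes = np.asarray(magnitudes, dtype=float)
    masses = np.asarray(masses, dtype=float)
    rng = np.random.default_rng(seed)

    baseline = fit_delay_scaling(
        _surface(task, masses, magnitudes, table, rtol, atol))
    if len(baseline) != len(magnitudes):
        raise SimulationError(
            f"baseline {task} surface incomplete at the requested magnitudes"
        )

    coef = np.full((n_draws, len(magnitudes)), np.nan)
    expo = np.full((n_draws, len(magnitudes)), np.nan)
    failures = 0
    for k in range(n_draws):
        sampled = sample_scaling_laws(table, rng, df=df)
        surf = _surface(task, masses, magnitudes, sampled, rtol, atol)
        fits = fit_delay_scaling(surf)
        if len(fits) != len(magnitudes):
            failures += 1
            continue
        coef[k] = [f.coefficient for f in fits]
        expo[k] = [f.exponent for f in fits]
    if failures > max_failure_fraction * n_draws:
        raise SimulationError(
            f"{failures}/{n_draws} Monte Carlo draws failed "
            f"(> {max_failure_fraction:.0%}); inputs too close to a "
            "feasibility boundary"
        )

    summaries = []
    for j, mag in enumerate(magnitudes):
        c = coef[:, j][np.isfinite(coef[:, j])]
        e = expo[:, j][np.isfinite(expo[:, j])]
        c0, e0 = baseline[j].coefficient, baseline[j].exponent
        c_half = 1.96 * float(np.std(c, ddof=1))
        e_half = 1.96 * float(np.std(e, ddof=1))
        summaries.append(
            MonteCarloSummary(
                task=task,
                magnitude=float(mag),
                n_draws=len(c),
                coefficient_samples=c,
                exponent_samples=e,
                coefficient_point=c0,
                exponent_point=e0,
                coefficient_ci=(c0 - c_half, c0 + c_half),
                exponent_ci=(e0 - e_half, e0 + e_half),
                seed=seed,
                n_failures=failures,
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[MonteCarloSummary]) -> pd.DataFrame:
    """Tabulate Monte Carlo summaries for CSV export."""
    return pd.DataFrame(
        {
            "task": [s.task for s in summaries],
            "magnitude": [s.magnitude for s in summaries],
            "coef_s": [s.coefficient_point for s in summaries],
            "coef_lo": [s.coefficient_ci[0] for s in summaries],
            "coef_hi": [s.coefficient_ci[1] for s in summaries],
            "exp": [s.exponent_point for s in summaries],
            "exp_lo": [s.exponent_ci[0] for s in summaries],
            "exp_hi": [s.exponent_ci[1] for s in summaries],
            "n_draws": [s.n_draws for s in summaries],
            "seed": [s.seed for s in summaries],
        }
    )
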