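"""Staged pipeline: simulate, fit, propagate, compare, report.

Each stage reads any upstream CSV artifacts from the output directory,
writes its own artifacts there, and records a JSON manifest (stage name,
config hash, package version, seed). Deterministic stages are idempotent:
re-running them rewrites byte-identical CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .allometry import (posture_scaling_table, swing_scaling_table,
                        write_parameter_table)
from .config import AnalysisConfig
from .monte_carlo import propagate, summaries_to_frame
from .powerlaw_fit import average_exponent, fit_delay_scaling, fits_to_frame
from .response_time import (build_sensorimotor_model, fit_crossover_law,
                            fit_relative_response_law, relative_response_time,
                            torque_sensitivity)
from .surfaces import DelaySurface
from .swing_sim import delay_surface_swing
from .posture_sim import delay_surface_posture
from .synthetic_data import generate_parameter_table

__all__ = ["run_stage", "STAGES"]

STAGES = ("swing", "posture", "fit", "montecarlo", "response", "report",
          "synth")


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is required but absent."""


def _write_manifest(outdir: Path, stage: str, config: AnalysisConfig,
                    seed: int | None = None) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.hash(),
        "package_version": __version__,
        "seed": seed,
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    config.to_yaml(outdir / "config.yaml")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name}; run the '{producer}' stage first"
        )
    return path


def _load_fits(outdir: Path, task: str):
    name = f"{task}_surface.csv"
    surface = DelaySurface.from_csv(_require(outdir / name, task))
    return fit_delay_scaling(surface)


def run_stage(stage: str, config: AnalysisConfig, outdir) -> dict:
    """Run one pipeline stage; returns a summary dict of what was written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    masses = config.masses()
    kwargs = dict(rtol=config.rtol, atol=config.atol,
                  gravity=config.gravity, density=config.muscle_density,
                  isometric_stress=config.isometric_stress)
    written: dict = {"stage": stage, "artifacts": []}

    if stage == "swing":
        surf = delay_surface_swing(masses, config.swing_magnitudes_deg,
                                   **kwargs)
        surf.to_csv(outdir / "swing_surface.csv")
        written["artifacts"].append("swing_surface.csv")
        written["complete"] = surf.complete

    elif stage == "posture":
        surf = delay_surface_posture(masses, config.posture_vnd, **kwargs)
        surf.to_csv(outdir / "posture_surface.csv")
        written["artifacts"].append("posture_surface.csv")
        written["complete"] = surf.complete

    elif stage == "fit":
        summary = {}
        for task, mag_name in (("swing", "magnitude_deg"), ("posture", "vnd")):
            fits = _load_fits(outdir, task)
            fits_to_frame(fits, mag_name).to_csv(
                outdir / f"{task}_fits.csv", index=False)
            written["artifacts"].append(f"{task}_fits.csv")
            summary[f"{task}_average_exponent"] = average_exponent(fits)
        (outdir / "fit_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written["artifacts"].append("fit_summary.json")
        written.update(summary)

    elif stage == "montecarlo":
        summaries = propagate(
            "swing", [config.mc_swing_magnitude_deg], config.mc_draws,
            config.mc_seed, swing_scaling_table(), masses,
            df=config.mc_df, rtol=config.rtol, atol=config.atol)
        summaries += propagate(
            "posture", [config.mc_posture_vnd], config.mc_draws,
            config.mc_seed + 1, posture_scaling_table(), masses,
            df=config.mc_df, rtol=config.rtol, atol=config.atol)
        summaries_to_frame(summaries).to_csv(
            outdir / "montecarlo_summary.csv", index=False)
        written["artifacts"].append("montecarlo_summary.csv")

    elif stage == "response":
        swing_fits = _load_fits(outdir, "swing")
        posture_fits = _load_fits(outdir, "posture")
        smd = build_sensorimotor_model(
            swing_fits, config.smd_anchor_deg,
            exponent=config.smd_exponent,
            coefficient_override=config.smd_coefficient_s)
        rows = []
        for task, fits in (("swing", swing_fits), ("posture", posture_fits)):
            law = fit_crossover_law(task, smd, fits, masses)
            rows.append({"task": task, "coefficient": law.coefficient,
                         "exponent": law.exponent})
        pd.DataFrame(rows).to_csv(outdir / "crossover_laws.csv", index=False)

        rel_fit = fit_relative_response_law(
            masses, config.smd_anchor_deg, smd, swing_fits,
            available_coefficient=config.available_coefficient_s,
            available_exponent=config.available_exponent)
        rel_rows = [{
            "mass_kg": m,
            "relative_response_time": relative_response_time(
                m, config.smd_anchor_deg, smd, swing_fits,
                available_coefficient=config.available_coefficient_s,
                available_exponent=config.available_exponent),
        } for m in masses]
        pd.DataFrame(rel_rows).to_csv(outdir / "relative_response.csv",
                                      index=False)
        sens = torque_sensitivity("swing", config.torque_factors, masses,
                                  config.swing_magnitudes_deg,
                                  rtol=config.rtol, atol=config.atol)
        sens.to_csv(outdir / "torque_sensitivity.csv", index=False)

        summary = {
            "smd_coefficient_s": smd.coefficient,
            "relative_response_coefficient": rel_fit.coefficient,
            "relative_response_exponent": rel_fit.exponent,
        }
        (outdir / "response_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written["artifacts"] += ["crossover_laws.csv", "relative_response.csv",
                                 "torque_sensitivity.csv",
                                 "response_summary.json"]
        written.update(summary)

    elif stage == "report":
        fit_summary = json.loads(
            _require(outdir / "fit_summary.json", "fit").read_text())
        report = dict(fit_summary)
        response_path = outdir / "response_summary.json"
        if response_path.exists():
            report.update(json.loads(response_path.read_text()))
        pd.DataFrame([report]).to_csv(outdir / "report.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        written["artifacts"] += ["report.csv", "report.json"]
        written.update(report)

    elif stage == "synth":
        for task, reference in (("swing", swing_scaling_table()),
                                ("posture", posture_scaling_table())):
            table = generate_parameter_table(reference, seed=config.mc_seed)
            write_parameter_table(
                table, outdir / f"synthetic_{task}_scaling.csv")
            written["artifacts"].append(f"synthetic_{task}_scaling.csv")

    seed = config.mc_seed if stage in ("montecarlo", "synth") else None
    _write_manifest(outdir, stage, config, seed)
    written["artifacts"].append(f"manifest_{stage}.json")
    return written
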