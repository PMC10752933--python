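"""Experiment orchestration: generate -> preprocess -> train -> evaluate ->
report, with a machine-readable manifest so every table and figure in the
output bundle can be regenerated from the config alone."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .evaluation import (
    EvaluationProtocol,
    EvaluationReport,
    baseline_identity,
    evaluate,
)
from .io import read_cohort
from .models import RecurrentConfig, count_parameters
from .preprocessing import preprocess_participant
from .synthetic import generate_cohort
from .training import Cohort, TrainingPlan, grid_search

logger = logging.getLogger(__name__)


def _plan(config: ExperimentConfig) -> TrainingPlan:
    t = config.training
    return TrainingPlan(
        learning_rate=t.learning_rate,
        weight_decay=t.weight_decay,
        batch_size=t.batch_size,
        epochs=t.epochs,
        seeds=tuple(t.base_seed + k for k in range(t.n_seeds)),
    )


def stage_generate(config: ExperimentConfig, outdir: Path) -> Path:
    cohort_dir = outdir / "cohort"
    generate_cohort(
        config.cohort.n_participants,
        config.cohort.n_days,
        config.cohort.seed,
        outdir=cohort_dir,
        truncate_one=config.cohort.truncate_one,
    )
    logger.info("cohort written to %s", cohort_dir)
    return cohort_dir


def stage_preprocess(config: ExperimentConfig, cohort_dir: Path) -> Cohort:
    streams, statics = read_cohort(cohort_dir)
    splits = {
        raw.participant_id: preprocess_participant(
            raw, config.preprocessing.split_fraction
        )
        for raw in streams
    }
    return Cohort.assemble(
        splits,
        {st.participant_id: st for st in statics},
        subset=config.model.static_subset,
    )


def stage_train(
    config: ExperimentConfig, cohort: Cohort, outdir: Path
) -> dict[tuple[str, int], object]:
    """Grid search per (integration, horizon); writes the audit log of
    per-epoch validation losses for every grid point."""
    plan = _plan(config)
    static_dim = (
        len(next(iter(cohort.statics.values()))) if cohort.statics else 0
    )
    grid = tuple(
        (l, u) for l in config.model.grid_layers for u in config.model.grid_units
    )
    fits: dict[tuple[str, int], object] = {}
    audit_rows = []
    for horizon_min in config.protocols.horizons_min:
        for integration in config.model.integrations:
            template = RecurrentConfig(
                cell=config.model.cell,
                dilated=config.model.dilated,
                integration=integration,
                static_dim=static_dim if integration != "none" else 0,
                horizon=horizon_min // 5,
                quantile_head=config.model.quantile_head,
            )
            from .training import grid_search

            fit = grid_search(plan, cohort, template, grid=grid)
            fits[(integration, horizon_min)] = fit
            for key, runs in fit.runs.items():
                for run in runs:
                    for epoch, vl in enumerate(run.val_losses):
                        audit_rows.append(
                            {
                                "integration": integration,
                                "horizon_min": horizon_min,
                                "n_layers": run.config.n_layers,
                                "n_units": run.config.n_units,
                                "seed": run.seed,
                                "epoch": epoch,
                                "val_loss": vl,
                            }
                        )
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(audit_rows).to_csv(outdir / "training_log.csv", index=False)
    leaderboards = []
    for (integration, horizon_min), fit in fits.items():
        lb = fit.leaderboard.copy()
        lb.insert(0, "horizon_min", horizon_min)
        leaderboards.append(lb)
    pd.concat(leaderboards, ignore_index=True).to_csv(
        outdir / "leaderboard.csv", index=False
    )
    return fits


def stage_evaluate(
    config: ExperimentConfig, cohort: Cohort, fits, outdir: Path
) -> pd.DataFrame:
    """Score best models and the identity baseline under every protocol;
    writes aggregate and per-participant tables plus Parkes summaries."""
    rows = []
    parkes_rows = []
    per_participant_frames = []
    for window in config.protocols.windows:
        for horizon_min in config.protocols.horizons_min:
            protocol = EvaluationProtocol(
                horizon_min=horizon_min, window_label=window
            )
            ident = EvaluationReport(
                protocol=protocol,
                entries=[
                    baseline_identity(split.test, protocol)
                    for split in cohort.splits.values()
                ],
            )
            models = {"identity": ident}
            for integration in config.model.integrations:
                fit = fits[(integration, horizon_min)]
                report = EvaluationReport(protocol=protocol)
                for run in fit.best_runs():
                    for pid, split in cohort.splits.items():
                        report.entries.append(
                            evaluate(
                                run.model,
                                split,
                                protocol,
                                statics=cohort.static_vector(pid),
                                seed=run.seed,
                                standardizer=cohort.standardizer_for(pid),
                            )
                        )
                label = config.model.cell + (
                    "+" if integration in ("cat", "both", "init") else ""
                )
                models[f"{label}:{integration}"] = report
            for name, report in models.items():
                pooled = report.pooled()
                avg = report.participant_average()
                rows.append(
                    {
                        "window": window,
                        "horizon_min": horizon_min,
                        "model": name,
                        "rmse": pooled["rmse"][0],
                        "rmse_se": pooled["rmse"][1],
                        "mape": pooled["mape"][0],
                        "mape_se": pooled["mape"][1],
                        "r2": pooled["r2"][0],
                        "r2_se": pooled["r2"][1],
                        "participant_avg_rmse": avg["rmse"][0],
                        "participant_sd_rmse": avg["rmse"][1],
                    }
                )
                pp = report.per_participant_frame()
                pp.insert(0, "model", name)
                pp.insert(0, "horizon_min", horizon_min)
                pp.insert(0, "window", window)
                per_participant_frames.append(pp)
                if window == "full_day" and horizon_min == min(
                    config.protocols.horizons_min
                ):
                    fig_path = outdir / f"parkes_{name.replace(':', '_')}.png"
                    fractions = report.parkes(
                        plot_path=fig_path,
                        title=f"{name}, PH {horizon_min} min",
                    )
                    parkes_rows.append(
                        {"model": name, "horizon_min": horizon_min, **fractions}
                    )
    outdir.mkdir(parents=True, exist_ok=True)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    pd.concat(per_participant_frames, ignore_index=True).to_csv(
        outdir / "per_participant.csv", index=False
    )
    pd.DataFrame(parkes_rows).to_csv(outdir / "parkes_summary.csv", index=False)
    return metrics


def run_experiment(config: ExperimentConfig | str | Path) -> Path:
    """Run the full pipeline; returns the output directory."""
    if not isinstance(config, ExperimentConfig):
        config = ExperimentConfig.from_yaml(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_dir = stage_generate(config, outdir)
    cohort = stage_preprocess(config, cohort_dir)
    fits = stage_train(config, cohort, outdir)
    stage_evaluate(config, cohort, fits, outdir)
    manifest = {
        "schema_version": config.schema_version,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seeds": list(_plan(config).seeds),
        "versions": {
            "glucast": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    config.to_yaml(outdir / "config.yaml")
    return outdir


__all__ = [
    "stage_generate",
    "stage_preprocess",
    "stage_train",
    "stage_evaluate",
    "run_experiment",
]
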