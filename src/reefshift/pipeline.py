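"""Pipeline configuration and the run-all orchestration."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, community, erfi, io, thermal
from .diversity import DEFAULT_BLEACHED_STATES, diversity_table, prevalence_table
from .errors import ConfigurationError, ReefshiftError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    output_dir: str = "reefshift_out"
    sst_path: str | None = None
    benthic_path: str | None = None
    belt_path: str | None = None
    logger_path: str | None = None
    baseline_years: list = field(default_factory=lambda: [1985, 1986, 1987, 1988, 1989, 1990, 1993])
    hotspot_offset: float = 0.5
    cool_offset: float = 0.5
    window_days: int = 84
    #: named (start, end) date windows; the SIMPER run uses simper_periods
    periods: dict = field(default_factory=dict)
    simper_periods: list = field(default_factory=list)  # [before_name, after_name]
    n_permutations: int = 100
    seed: int = 0
    erfi_window: list = field(default_factory=list)  # [start, end]
    direction_weights: dict = field(default_factory=lambda: dict(erfi.DEFAULT_DIRECTION_WEIGHTS))
    bleached_states: list = field(default_factory=lambda: sorted(DEFAULT_BLEACHED_STATES))

    def climatology_config(self) -> thermal.ClimatologyConfig:
        return thermal.ClimatologyConfig(
            baseline_years=frozenset(self.baseline_years),
            hotspot_offset=self.hotspot_offset,
            cool_offset=self.cool_offset,
            window_days=self.window_days,
        )


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a JSON or YAML file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return PipelineConfig(**data)


def _round_trip_safe(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage, writing stage CSVs, a run log and a
    summary JSON to ``config.output_dir``. Returns the summary dict.

    A stage failure aborts with the stage name; a partial-output manifest
    is still written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "outputs": []}
    current_stage = "setup"

    def _write(df: pd.DataFrame, name: str):
        path = out / name
        _round_trip_safe(df, path)
        summary["outputs"].append(name)

    try:
        if config.sst_path:
            current_stage = "thermal"
            series = io.read_sst(config.sst_path)
            clim_cfg = config.climatology_config()
            clim = thermal.compute_climatology(series, clim_cfg)
            dhw = thermal.compute_dhw(series, clim, clim_cfg)
            exceed = thermal.annual_exceedance(series, clim)
            fit = thermal.fit_trend(series.index, series.to_numpy())
            _write(
                pd.DataFrame({"month": range(1, 13), "mean_c": clim.monthly_mean}),
                "climatology.csv",
            )
            _write(
                pd.DataFrame({"date": dhw.index.date, "dhw_c_weeks": dhw.to_numpy()}),
                "dhw.csv",
            )
            _write(exceed.reset_index(), "annual_exceedance.csv")
            summary["stages"]["thermal"] = {
                "mmm": round(clim.mmm, 4),
                "bleaching_threshold": round(clim.bleaching_threshold, 4),
                "trend_c_per_decade": round(thermal.slope_per_decade(fit), 4),
                "max_sst": round(float(series.max()), 4),
            }
        else:
            summary["stages"]["thermal"] = "skipped (no sst_path)"

        if config.logger_path:
            current_stage = "logger"
            monthly = thermal.aggregate_logger(io.read_logger(config.logger_path))
            _write(monthly, "logger_monthly.csv")
            summary["stages"]["logger"] = {"rows": int(len(monthly))}

        benthic = io.read_benthic(config.benthic_path) if config.benthic_path else None
        belt = io.read_belt(config.belt_path) if config.belt_path else None

        if benthic is not None and config.simper_periods:
            current_stage = "simper"
            if len(config.simper_periods) != 2:
                raise ConfigurationError("simper_periods must name exactly two windows")
            windows = {name: config.periods[name] for name in config.simper_periods}
            matrix = io.assign_periods(benthic, windows)
            matrix, n_imputed = community.impute_missing(matrix)
            result = community.simper(
                matrix,
                n_permutations=config.n_permutations,
                seed=config.seed,
                periods=tuple(config.simper_periods),
            )
            _write(result.table.reset_index(), "simper.csv")
            summary["stages"]["simper"] = {
                "mean_dissimilarity": round(result.mean_dissimilarity, 6),
                "imputed_cells": n_imputed,
                "periods": list(result.periods),
            }

        if belt is not None:
            current_stage = "diversity"
            div = diversity_table(belt)
            prev = prevalence_table(belt, frozenset(config.bleached_states))
            _write(div, "diversity.csv")
            _write(prev, "prevalence.csv")
            summary["stages"]["diversity"] = {
                "transects": int(len(div)),
                "mean_shannon": round(float(div["shannon_h"].mean()), 4),
            }

        if benthic is not None and belt is not None and config.erfi_window:
            current_stage = "erfi"
            report = erfi.run_erfi(
                benthic,
                belt,
                tuple(config.erfi_window),
                direction_weights=config.direction_weights,
                bleached_states=frozenset(config.bleached_states),
            )
            scores = pd.DataFrame(
                {
                    "site": report.scores.raw.index,
                    "raw": report.scores.raw.to_numpy(),
                    "normalized": report.scores.normalized.to_numpy(),
                }
            )
            scores["rank"] = scores["raw"].rank(ascending=False).astype(int)
            _write(scores.sort_values("rank"), "erfi_scores.csv")
            wdf = report.weights.loadings.copy()
            wdf["L"] = report.weights.L
            wdf["D"] = report.weights.D
            wdf["C"] = report.weights.C
            _write(wdf.reset_index(names="variable"), "erfi_weights.csv")
            (out / "erfi_provenance.json").write_text(
                json.dumps(report.provenance, indent=2, sort_keys=True)
            )
            summary["outputs"].append("erfi_provenance.json")
            summary["stages"]["erfi"] = {
                "ranking": report.scores.ranking,
                "raw": {s: round(v, 4) for s, v in report.scores.raw.items()},
            }
    except ReefshiftError as exc:
        manifest = {"failed_stage": current_stage, "error": str(exc), "outputs": summary["outputs"]}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    run_log = {
        "reefshift_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {k: getattr(config, k) for k in PipelineConfig.__dataclass_fields__},
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True, default=str))
    summary["outputs"].append("run_log.json")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
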