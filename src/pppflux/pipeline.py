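"""Pipeline orchestration: configuration, QC, and end-to-end runs.

A run chains simulate (or load) -> optional natural-abundance correction ->
steady-state labelling QC -> CSTR Monte Carlo fitting -> treatment-vs-control
comparison, writing all tabular outputs plus a reproducibility manifest
(configuration, master seed, software version) to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cstr import DEFAULT_TARGETS, ComparisonResult, compare_all
from .io import read_timecourse, to_fractions, correct_table, write_timecourse
from .simulate import (
    PAPER_TIME_GRID_S,
    NetworkConfig,
    NoiseModel,
    TracerSpec,
    default_scenarios,
    generate_experiment,
)

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SteadyStateQC",
    "qc_steady_state",
    "run_pipeline",
    "load_run_config",
    "scenarios_from_config",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    output_dir: str = "pppflux_out"
    input_path: str | None = None  # long-format CSV; None -> simulate
    control_condition: str = "siCon"
    targets: tuple[tuple[str, int], ...] = DEFAULT_TARGETS
    n_draws: int = 1000
    seed: int = 0
    p13C: float = 0.0107
    correction: bool = False
    qc_reference: str = "G6P"
    qc_threshold: float = 0.05
    # simulation block (ignored when input_path is given)
    times: tuple[float, ...] = PAPER_TIME_GRID_S
    replicates: int = 3
    noise_sd: float = 0.01
    tracer_fraction: float = 0.5
    purity: float = 1.0
    knockdown_scale: float = 0.4
    scenarios: dict[str, NetworkConfig] | None = None

    def resolved_scenarios(self) -> dict[str, NetworkConfig]:
        if self.scenarios is not None:
            return self.scenarios
        return default_scenarios(knockdown_scale=self.knockdown_scale)


@dataclass(frozen=True)
class SteadyStateQC:
    """Per-condition mean enrichment of the reference metabolite at the last
    time point, with replicate spread and absolute difference vs control."""

    reference: str
    control: str
    threshold: float
    table: pd.DataFrame
    flagged: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.flagged


def qc_steady_state(
    table: pd.DataFrame,
    reference: str = "G6P",
    control: str = "siCon",
    threshold: float = 0.05,
) -> SteadyStateQC:
    """Check that all conditions reached the same isotopic steady state.

    Computes the mean 13C enrichment of the reference metabolite (default
    G6P) at the final time point per condition and flags any condition whose
    mean differs from control by more than ``threshold`` (absolute).  A flag
    means branch fluxes cannot be compared across conditions without first
    correcting for unequal precursor labelling.
    """
    table = to_fractions(table)
    sub = table[table["metabolite"] == reference]
    if sub.empty:
        raise ValueError(f"reference metabolite {reference!r} not in table")
    t_final = sub["time_s"].max()
    sub = sub[sub["time_s"] == t_final]
    conditions = list(dict.fromkeys(table["condition"]))
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not in table")
    rows = []
    for condition in conditions:
        csub = sub[sub["condition"] == condition]
        if csub.empty:
            raise ValueError(
                f"reference metabolite {reference!r} missing at t={t_final}s "
                f"for condition {condition!r}"
            )
        per_rep = (
            csub.assign(weighted=csub["mass_shift"] * csub["value"])
            .groupby("replicate")
            .apply(
                lambda g: g["weighted"].sum() / g["n_carbons"].iloc[0],
                include_groups=False,
            )
        )
        rows.append(
            dict(
                condition=condition,
                enrichment_mean=float(per_rep.mean()),
                enrichment_sd=float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0,
                n_replicates=len(per_rep),
            )
        )
    qc = pd.DataFrame(rows)
    control_mean = float(qc.loc[qc["condition"] == control, "enrichment_mean"].iloc[0])
    qc["abs_diff_vs_control"] = (qc["enrichment_mean"] - control_mean).abs()
    qc["flagged"] = qc["abs_diff_vs_control"] > threshold
    flagged = tuple(qc.loc[qc["flagged"], "condition"])
    if flagged:
        logger.warning(
            "steady-state QC: conditions %s differ from %s by > %.3f in %s enrichment",
            flagged, control, threshold, reference,
        )
    return SteadyStateQC(reference, control, threshold, qc, flagged)


def _config_to_jsonable(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.scenarios is not None:
        d["scenarios"] = {
            name: dataclasses.asdict(cfg) for name, cfg in config.scenarios.items()
        }
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write outputs under ``config.output_dir``.

    Stages run in order (simulate/load, correct, QC, fit+compare); each stage
    logs its completion and leaves its outputs on disk even if a later stage
    fails.  Identical configuration and seed give byte-identical numeric
    outputs.  Returns a dict with the in-memory results and output paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "pppflux",
        "version": __version__,
        "seed": config.seed,
        "config": _config_to_jsonable(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    if config.input_path is not None:
        table = read_timecourse(config.input_path)
        logger.info("stage load: %d rows from %s", len(table), config.input_path)
    else:
        table = generate_experiment(
            config.resolved_scenarios(),
            TracerSpec(config.tracer_fraction, config.purity),
            np.asarray(config.times, dtype=float),
            config.replicates,
            NoiseModel(sd_fraction=config.noise_sd, seed=config.seed),
        )
        logger.info("stage simulate: %d rows, seed %d", len(table), config.seed)
    write_timecourse(table, out / "measurements.csv")

    table = to_fractions(table)
    if config.correction:
        table = correct_table(table, config.p13C)
        write_timecourse(table, out / "measurements_corrected.csv")
        logger.info("stage correct: natural abundance removed at p13C=%.4f", config.p13C)
    manifest["correction_applied"] = config.correction
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    qc = qc_steady_state(
        table, config.qc_reference, config.control_condition, config.qc_threshold
    )
    qc.table.to_csv(out / "qc_steady_state.csv", index=False)
    logger.info("stage qc: flagged=%s", list(qc.flagged) or "none")

    comparison: ComparisonResult = compare_all(
        table,
        config.control_condition,
        targets=config.targets,
        n_draws=config.n_draws,
        seed=config.seed,
    )
    comparison.report.to_csv(out / "comparison.csv", index=False)
    comparison.residuals.to_csv(out / "fit_residuals.csv", index=False)
    dropped = {f"{k[0]}/{k[1]}/m{k[2]}": f.n_dropped for k, f in comparison.fits.items()}
    logger.info("stage compare: %d rows, dropped draws %s", len(comparison.report), dropped)

    return {
        "table": table,
        "qc": qc,
        "comparison": comparison,
        "output_dir": out,
        "paths": {
            "measurements": out / "measurements.csv",
            "qc": out / "qc_steady_state.csv",
            "comparison": out / "comparison.csv",
            "residuals": out / "fit_residuals.csv",
            "manifest": out / "manifest.json",
        },
    }


# --- TOML configuration ----------------------------------------------------

_RUN_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def scenarios_from_config(block: dict, where: str = "scenarios") -> dict[str, NetworkConfig]:
    scenarios = {}
    for name, params in block.items():
        if not isinstance(params, dict):
            raise ValueError(f"{where}.{name}: expected a table of pools/fluxes")
        try:
            scenarios[name] = NetworkConfig(**params)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{where}.{name}: {exc}") from exc
    return scenarios


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a TOML run configuration.

    Layout: a ``[run]`` table with RunConfig fields, an optional
    ``[simulation]`` table (times, replicates, noise_sd, tracer_fraction,
    purity, knockdown_scale) and optional ``[scenarios.<name>]`` tables with
    NetworkConfig fields.  Schema violations raise ValueError naming the
    offending field path.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    kwargs: dict = {}
    for section in ("run", "simulation"):
        for key, value in raw.get(section, {}).items():
            if key not in _RUN_FIELDS:
                raise ValueError(f"{section}.{key}: unknown configuration field")
            kwargs[key] = value
    if "scenarios" in raw:
        kwargs["scenarios"] = scenarios_from_config(raw["scenarios"])
    if "times" in kwargs:
        kwargs["times"] = tuple(float(t) for t in kwargs["times"])
    if "targets" in kwargs:
        kwargs["targets"] = tuple(
            (str(m), int(s)) for m, s in kwargs["targets"]
        )
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"run configuration invalid: {exc}") from exc
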