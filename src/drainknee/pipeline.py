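"""Orchestration: simulate -> sample -> analyze -> report for the three arms.

One :class:`RunConfig` drives the whole workflow deterministically: a master
seed is split into per-stage substreams, every output CSV embeds its units in
the column names (times in hours, flows in mL/min, concentrations in µg/mL),
and a manifest records the seed, package version and full configuration so
any output can be reproduced byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import AUC_WINDOWS_H, ThresholdBand, exposure_summary
from .depots import ARMS, default_depots
from .flow import (
    DEFAULT_INITIAL_CAP_ML_MIN,
    DrainageTrendline,
    build_stepwise_schedule,
)
from .reactor import ReactorConfig, simulate
from .sampling import MeasurementModel, SamplingSchedule, sample_effluent, write_dataset_csv
from .zoi import PAO1, UAMS1, ZoiCalibration, potency_series

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger("drainknee")


@dataclass
class RunConfig:
    """Complete description of one pipeline run."""

    arms: tuple[str, ...] = ARMS
    volume_ml: float = 75.0
    duration_h: float = 48.0
    solver_step_min: float = 0.1
    trendline_coefficient: float = 3.1269
    trendline_exponent: float = -1.019
    initial_cap_ml_min: float = DEFAULT_INITIAL_CAP_ML_MIN
    n_replicates: int = 3
    lod_ug_ml: float = 0.98
    noise_sigma_log10: float = 0.15
    censor_to: str = "lod"
    auc_windows_h: tuple[float, ...] = AUC_WINDOWS_H
    threshold_low_ug_ml: float = 100.0
    threshold_high_ug_ml: float = 750.0
    threshold_duration_h: float = 24.0
    zoi_slope_mm_per_doubling: float = 2.0
    seed: int = 0
    outdir: str = "drainknee_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "arms" in raw:
            raw["arms"] = tuple(raw["arms"])
        if "auc_windows_h" in raw:
            raw["auc_windows_h"] = tuple(raw["auc_windows_h"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["arms"] = list(d["arms"])
        d["auc_windows_h"] = list(d["auc_windows_h"])
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Collect invariant violations as messages naming the offending key."""
    v: list[str] = []
    unknown = set(config.arms) - set(ARMS)
    if unknown:
        v.append(f"arms: unknown arm(s) {sorted(unknown)}")
    if not config.arms:
        v.append("arms: at least one arm is required")
    if config.volume_ml <= 0:
        v.append("volume_ml: reactor volume must be > 0")
    if config.duration_h <= 0:
        v.append("duration_h: must be > 0")
    if config.solver_step_min <= 0:
        v.append("solver_step_min: must be > 0")
    if config.trendline_coefficient <= 0:
        v.append("trendline_coefficient: must be > 0")
    if config.trendline_exponent >= 0:
        v.append("trendline_exponent: must be < 0")
    if config.initial_cap_ml_min <= 0:
        v.append("initial_cap_ml_min: must be > 0")
    if config.n_replicates < 1:
        v.append("n_replicates: must be >= 1")
    if config.lod_ug_ml <= 0:
        v.append("lod_ug_ml: must be > 0")
    if config.noise_sigma_log10 < 0:
        v.append("noise_sigma_log10: must be >= 0")
    if config.censor_to not in ("lod", "zero"):
        v.append("censor_to: must be 'lod' or 'zero'")
    for w in config.auc_windows_h:
        if w > config.duration_h:
            v.append(f"auc_windows_h: window {w} h exceeds duration_h {config.duration_h} h")
    if not 0 < config.threshold_low_ug_ml <= config.threshold_high_ug_ml:
        v.append("threshold_low_ug_ml: need 0 < low <= high")
    if config.threshold_duration_h > config.duration_h:
        v.append("threshold_duration_h: exceeds duration_h")
    if config.zoi_slope_mm_per_doubling < 0:
        v.append("zoi_slope_mm_per_doubling: must be >= 0")
    return v


def _stage(msg: str) -> None:
    logger.info(msg)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full workflow and write the report bundle to ``config.outdir``.

    Returns a mapping of artifact name to written path.  Identical
    config + seed yields byte-identical outputs.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    trendline = DrainageTrendline(config.trendline_coefficient, config.trendline_exponent)
    schedule = build_stepwise_schedule(
        trendline,
        initial_cap_ml_min=config.initial_cap_ml_min,
        duration_h=config.duration_h,
    )
    _stage("[schedule] built stepwise drainage schedule")
    paths["schedule"] = outdir / "schedule.csv"
    schedule.to_frame().to_csv(paths["schedule"], index=False)

    sampling_times = tuple(
        t for t in SamplingSchedule().times_h if t <= config.duration_h
    )
    sampling = SamplingSchedule(times_h=sampling_times)
    measurement = MeasurementModel(
        lod_ug_ml=config.lod_ug_ml,
        noise_sigma_log10=config.noise_sigma_log10,
        censor_to=config.censor_to,
    )

    arm_streams = dict(zip(ARMS, np.random.SeedSequence(config.seed).spawn(len(ARMS))))
    datasets = []
    for arm in config.arms:
        _stage(f"[simulate] arm={arm}")
        result = simulate(
            ReactorConfig(
                schedule=schedule,
                depots=default_depots(arm),
                volume_ml=config.volume_ml,
                duration_h=config.duration_h,
                solver_step_min=config.solver_step_min,
                arm=arm,
            )
        )
        sim_path = outdir / f"simulation_{arm}.csv"
        # thin the dense solver grid to sampling resolution for the CSV
        result.to_frame().to_csv(sim_path, index=False)
        paths[f"simulation_{arm}"] = sim_path
        _stage(f"[fixtures] arm={arm}")
        datasets.append(
            sample_effluent(
                result.series,
                schedule=sampling,
                measurement=measurement,
                n_replicates=config.n_replicates,
                seed=arm_streams[arm],
            )
        )
    dataset = pd.concat(datasets, ignore_index=True)
    paths["measurements"] = outdir / "measurements.csv"
    write_dataset_csv(dataset, paths["measurements"])

    _stage("[analyze] exposure metrics")
    band = ThresholdBand(
        config.threshold_low_ug_ml, config.threshold_high_ug_ml, config.threshold_duration_h
    )
    summary = exposure_summary(
        dataset, windows_h=config.auc_windows_h, band=band, lod_ug_ml=config.lod_ug_ml
    )
    paths["log_summary"] = outdir / "log_summary.csv"
    summary.log_summary.to_csv(paths["log_summary"], index=False)
    paths["auc"] = outdir / "auc.csv"
    summary.auc.to_csv(paths["auc"], index=False)
    paths["threshold"] = outdir / "time_above_threshold.csv"
    summary.threshold.to_csv(paths["threshold"], index=False)
    if summary.log_diff is not None:
        paths["log_difference"] = outdir / "log_difference.csv"
        summary.log_diff.to_csv(paths["log_difference"], index=False)
    if summary.tests is not None:
        paths["ttests"] = outdir / "ttests.csv"
        summary.tests.to_csv(paths["ttests"], index=False)

    _stage("[analyze] predicted zones of inhibition")
    calib = ZoiCalibration(slope_mm_per_doubling=config.zoi_slope_mm_per_doubling)
    for organism, tag in ((UAMS1, "uams1"), (PAO1, "pao1")):
        zoi = potency_series(dataset, organism, calib)
        paths[f"zoi_{tag}"] = outdir / f"zoi_{tag}.csv"
        zoi.to_csv(paths[f"zoi_{tag}"], index=False)

    paths["report"] = outdir / "report.txt"
    paths["report"].write_text(summary.report() + "\n")

    manifest = {
        "package": "drainknee",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {k: p.name for k, p in paths.items()},
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _stage("[done] wrote " + str(outdir))
    return paths
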