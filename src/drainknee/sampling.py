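"""Synthetic effluent measurement: sampling schedule, LOD censoring, noise.

Emulates LCMS quantification of 2.5 mL effluent samples drawn from the
simulated reactor at the clinical sampling times.  Measurement error is
multiplicative lognormal (concentration assays err multiplicatively), and
values below the assay's limit of detection are censored.  Censored values
are recorded AT the LOD (0.98 µg/mL, i.e. -0.01 on the log10 scale) by
default, matching the reporting convention for the real assay; zero
substitution is available as a sensitivity option.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .depots import ARMS
from .flow import CLINICAL_SAMPLING_TIMES_H
from .reactor import ConcentrationSeries, SimulationResult, simulate_arm

__all__ = [
    "SamplingSchedule",
    "MeasurementModel",
    "DATASET_COLUMNS",
    "sample_effluent",
    "generate_arm_fixtures",
    "read_dataset_csv",
    "write_dataset_csv",
]

#: Interchange schema for measured effluent datasets (synthetic or real LCMS).
DATASET_COLUMNS = ("arm", "replicate", "time_h", "antibiotic", "conc_ug_ml", "censored")


@dataclass(frozen=True)
class SamplingSchedule:
    """Effluent sampling times (h) and the manual sample volume (mL)."""

    times_h: tuple[float, ...] = CLINICAL_SAMPLING_TIMES_H
    sample_volume_ml: float = 2.5

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.sample_volume_ml <= 0:
            raise ValueError("sample volume must be > 0")


@dataclass(frozen=True)
class MeasurementModel:
    """Assay model: detection limit, log10-scale noise, censoring rule."""

    lod_ug_ml: float = 0.98
    noise_sigma_log10: float = 0.15
    censor_to: str = "lod"  # {"lod", "zero"}: value recorded for censored samples

    def __post_init__(self) -> None:
        if self.lod_ug_ml <= 0:
            raise ValueError("LOD must be > 0")
        if self.noise_sigma_log10 < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.censor_to not in ("lod", "zero"):
            raise ValueError("censor_to must be 'lod' or 'zero'")

    def censor(self, measured: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Apply the detection limit; returns (recorded values, censored mask)."""
        measured = np.asarray(measured, dtype=float)
        mask = measured < self.lod_ug_ml
        fill = self.lod_ug_ml if self.censor_to == "lod" else 0.0
        return np.where(mask, fill, measured), mask


def sample_effluent(
    series: ConcentrationSeries,
    schedule: SamplingSchedule | None = None,
    measurement: MeasurementModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Measure a simulated concentration series at the sampling schedule.

    Per replicate and time point the true concentration is perturbed by
    independent multiplicative lognormal noise (``measured = true * 10**(σ z)``,
    z standard normal) and censored below the LOD.  Replicates use distinct,
    reproducible substreams spawned from ``seed``; the same seed always yields
    the identical dataset.
    """
    schedule = schedule or SamplingSchedule()
    measurement = measurement or MeasurementModel()
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    times = np.asarray(schedule.times_h, dtype=float)

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(n_replicates)
    records = []
    for ab in series.concentrations_ug_ml:
        truth = series.interp(ab, times)  # raises if schedule exceeds the series
        for rep, stream in enumerate(streams, start=1):
            rng = np.random.default_rng(stream)
            z = rng.standard_normal(times.size)
            measured = truth * 10.0 ** (measurement.noise_sigma_log10 * z)
            recorded, censored = measurement.censor(measured)
            records.append(
                pd.DataFrame(
                    {
                        "arm": series.arm,
                        "replicate": rep,
                        "time_h": times,
                        "antibiotic": ab,
                        "conc_ug_ml": recorded,
                        "censored": censored.astype(int),
                    }
                )
            )
    return pd.concat(records, ignore_index=True)[list(DATASET_COLUMNS)]


def generate_arm_fixtures(
    arms: Sequence[str] = ARMS,
    n_replicates: int = 3,
    seed: int = 0,
    measurement: MeasurementModel | None = None,
    schedule: SamplingSchedule | None = None,
    duration_h: float = 48.0,
    solver_step_min: float = 0.1,
) -> pd.DataFrame:
    """Forward-simulate each arm under reference settings and measure it.

    This is the package's standard synthetic dataset: three administration
    arms, three replicates each, lognormal assay noise, LOD censoring.  Per-arm
    sampling uses substreams of ``seed`` so adding an arm does not reshuffle
    the others.
    """
    unknown = set(arms) - set(ARMS)
    if unknown:
        raise ValueError(f"unknown arms {sorted(unknown)}; expected subset of {ARMS}")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    arm_seeds = dict(zip(ARMS, root.spawn(len(ARMS))))
    frames = []
    for arm in arms:
        result = simulate_arm(arm, duration_h=duration_h, solver_step_min=solver_step_min)
        frames.append(
            sample_effluent(
                result.series,
                schedule=schedule,
                measurement=measurement,
                n_replicates=n_replicates,
                seed=arm_seeds[arm],
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_dataset_csv(dataset: pd.DataFrame, path) -> None:
    """Write a measured dataset in the interchange CSV schema."""
    dataset[list(DATASET_COLUMNS)].to_csv(path, index=False)


def read_dataset_csv(path) -> pd.DataFrame:
    """Read a measured dataset (synthetic or real LCMS export)."""
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset CSV missing required columns: {sorted(missing)}")
    return df[list(DATASET_COLUMNS)]
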