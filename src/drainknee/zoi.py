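"""Kirby-Bauer zone-of-inhibition prediction from effluent concentrations.

A disc-diffusion plate is stood in for by a calibration model: zone diameter
grows log-linearly in concentration above the organism's MIC (standard
disc-diffusion theory gives diameter roughly linear in log concentration),
with a default slope of 2 mm per doubling of C/MIC.  At or below the MIC the
zone collapses to the disc itself (growth up to the disc edge = no potency).
Predicted diameters are comparable in shape and ordering to plate data, not
in absolute millimetres, because the slope is a model choice, not a measured
calibration.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .depots import TOBRAMYCIN, VANCOMYCIN

__all__ = [
    "Mic",
    "OrganismProfile",
    "ZoiCalibration",
    "PAO1",
    "UAMS1",
    "predict_zoi",
    "potency_series",
]


@dataclass(frozen=True)
class Mic:
    """Minimum inhibitory concentration (µg/mL), optionally an open '>' bound.

    An open-above MIC (e.g. "> 64") is read conservatively: no inhibition is
    credited unless the concentration exceeds the bound, and above the bound
    the bound itself stands in for the unknown MIC.
    """

    value_ug_ml: float
    open_above: bool = False

    def __post_init__(self) -> None:
        if self.value_ug_ml <= 0:
            raise ValueError("MIC must be > 0")


@dataclass(frozen=True)
class OrganismProfile:
    """Reference organism with per-antibiotic MICs."""

    name: str
    mic: Mapping[str, Mic]


#: Pseudomonas aeruginosa PAO1: tobramycin-susceptible, vancomycin-resistant
#: (MIC reported only as > 64 µg/mL).
PAO1 = OrganismProfile(
    "Pseudomonas aeruginosa PAO1",
    {TOBRAMYCIN: Mic(1.5), VANCOMYCIN: Mic(64.0, open_above=True)},
)

#: Staphylococcus aureus UAMS-1: susceptible to both agents.
UAMS1 = OrganismProfile(
    "Staphylococcus aureus UAMS-1",
    {TOBRAMYCIN: Mic(2.0), VANCOMYCIN: Mic(2.0)},
)


@dataclass(frozen=True)
class ZoiCalibration:
    """Concentration -> zone-diameter calibration.

    ``slope_mm_per_doubling`` is the diameter gained per doubling of C/MIC;
    ``disc_diameter_mm`` is the filter disc itself (7 mm), the floor of any
    predicted zone.
    """

    disc_diameter_mm: float = 7.0
    slope_mm_per_doubling: float = 2.0

    def __post_init__(self) -> None:
        if self.disc_diameter_mm <= 0:
            raise ValueError("disc diameter must be > 0")
        if self.slope_mm_per_doubling < 0:
            raise ValueError("calibration slope must be >= 0")


def predict_zoi(
    concentrations_ug_ml: Mapping[str, float],
    organism: OrganismProfile,
    calibration: ZoiCalibration | None = None,
) -> float:
    """Predicted zone diameter (mm) for one effluent sample.

    Per agent: ``disc + slope * log2(C / MIC)`` when C exceeds the MIC,
    otherwise the bare disc.  Agents whose MIC is an open bound contribute
    nothing unless C exceeds the bound.  The combined zone is the maximum
    single-agent zone (independent action, no synergy), so it is invariant
    to adding an agent at zero concentration and never falls below the disc.
    """
    calibration = calibration or ZoiCalibration()
    d = calibration.disc_diameter_mm
    for ab, conc in concentrations_ug_ml.items():
        if conc < 0:
            raise ValueError("concentrations must be >= 0")
        mic = organism.mic.get(ab)
        if mic is None or conc <= mic.value_ug_ml:
            continue
        d_agent = calibration.disc_diameter_mm + calibration.slope_mm_per_doubling * np.log2(
            conc / mic.value_ug_ml
        )
        d = max(d, d_agent)
    return float(d)


def potency_series(
    dataset: pd.DataFrame,
    organism: OrganismProfile,
    calibration: ZoiCalibration | None = None,
) -> pd.DataFrame:
    """Predicted ZOI time course per arm: mean ± SE across replicates.

    Each replicate's sample combines that replicate's concentrations of every
    antibiotic present at that time point.
    """
    calibration = calibration or ZoiCalibration()
    rows = []
    for (arm, rep, t), grp in dataset.groupby(["arm", "replicate", "time_h"], sort=True):
        conc = dict(zip(grp["antibiotic"], grp["conc_ug_ml"].astype(float)))
        rows.append(
            {
                "arm": arm,
                "replicate": rep,
                "time_h": t,
                "zoi_mm": predict_zoi(conc, organism, calibration),
            }
        )
    per_rep = pd.DataFrame(rows)
    out = (
        per_rep.groupby(["arm", "time_h"], sort=True)["zoi_mm"]
        .agg(mean_zoi_mm="mean", sd="std", n="count")
        .reset_index()
    )
    out["se_mm"] = (out["sd"] / np.sqrt(out["n"])).fillna(0.0)
    out["organism"] = organism.name
    return out[["organism", "arm", "time_h", "mean_zoi_mm", "se_mm", "n"]]
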