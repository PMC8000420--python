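"""Minimal figures: per-arm concentration profiles and AUC bars."""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .reactor import SimulationResult


def plot_concentration_profiles(results: Sequence[SimulationResult], lod_ug_ml: float = 0.98):
    """Concentration vs time for each arm, one panel per antibiotic.

    Log10 concentration axis with the detection limit marked; log2 time axis
    so the rapidly sampled early phase is readable.
    """
    import matplotlib.pyplot as plt

    antibiotics = sorted({ab for r in results for ab in r.series.concentrations_ug_ml})
    fig, axes = plt.subplots(1, len(antibiotics), figsize=(6 * len(antibiotics), 4),
                             squeeze=False)
    for ax, ab in zip(axes[0], antibiotics):
        for r in results:
            if ab not in r.series.concentrations_ug_ml:
                continue
            t = r.series.times_h
            c = np.maximum(r.series.concentrations_ug_ml[ab], 1e-3)
            ax.plot(t[1:], c[1:], label=r.series.arm or "simulated")
        ax.axhline(lod_ug_ml, ls="--", color="grey", lw=1, label="LOD")
        ax.set_xscale("log", base=2)
        ax.set_yscale("log")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (µg/mL)")
        ax.set_title(ab)
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_auc(auc_table, antibiotic: str):
    """Geometric-mean AUC per arm across exposure windows."""
    import matplotlib.pyplot as plt

    sub = auc_table[auc_table["antibiotic"] == antibiotic]
    gm = (
        sub.groupby(["arm", "window_h"])["auc_ug_h_ml"]
        .agg(lambda x: 10 ** np.mean(np.log10(np.maximum(x, 1e-12))))
        .unstack("arm")
    )
    ax = gm.plot.bar(logy=True, rot=0)
    ax.set_xlabel("window (h)")
    ax.set_ylabel("geometric-mean AUC (µg·h/mL)")
    ax.set_title(antibiotic)
    return ax.figure
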