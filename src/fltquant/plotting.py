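"""Plot rendering (headless-safe) for histograms and growth curves."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_histograms", "plot_growth_curves"]


def plot_histograms(histograms: Sequence, path: str | Path) -> Path:
    """Overlay fractional-frequency curves at bin centers."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, h in enumerate(histograms):
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        ax.plot(centers, h.fractional_frequency, drawstyle="steps-mid",
                label=h.source_id or f"hist_{i}")
    ax.set_xlabel("SUV")
    ax.set_ylabel("fractional frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_growth_curves(summary: pd.DataFrame, path: str | Path) -> Path:
    """Mean +/- SD percent-change-from-baseline curves per arm."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for arm, grp in summary.groupby("arm"):
        grp = grp.sort_values("day")
        ax.errorbar(grp["day"], grp["mean"], yerr=grp["sd"], marker="o",
                    capsize=3, label=arm)
    ax.axhline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("day")
    ax.set_ylabel("tumor volume change from baseline (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
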