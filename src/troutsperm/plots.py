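"""A single figure: flagellum-to-head-area ratio by acclimation group."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_ratio_by_group"]


def plot_ratio_by_group(derived: pd.DataFrame, path: str | Path | None = None,
                        measure: str = "ratio_LF_AH_per_um"):
    """Box plot of a per-cell measure by group with raw cells and male means.

    Mirrors the classic ratio-by-group figure: per-group box (median, IQR),
    group mean marker, jittered raw cells in grey and per-male means in black.
    """
    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    groups = ["cold", "warm"]
    data = [derived.loc[derived["group"] == g, measure].to_numpy() for g in groups]
    ax.boxplot(data, positions=[1, 2], widths=0.45, showmeans=True,
               meanprops=dict(marker="x", markeredgecolor="black"))
    for i, g in enumerate(groups, start=1):
        y = derived.loc[derived["group"] == g, measure]
        ax.plot(i + rng.uniform(-0.12, 0.12, len(y)), y, "o",
                color="0.7", ms=3, alpha=0.6, zorder=1)
        mm = derived[derived["group"] == g].groupby("male_id")[measure].mean()
        ax.plot(np.full(len(mm), i + 0.28), mm, "o", color="black", ms=4)
    ax.set_xticks([1, 2])
    ax.set_xticklabels(["cold (8 °C)", "warm (13 °C)"])
    ax.set_ylabel(r"$L_F / A_H$ ($\mu m^{-1}$)" if measure == "ratio_LF_AH_per_um"
                  else measure)
    ax.set_xlabel("Acclimation temperature")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
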