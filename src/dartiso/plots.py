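"""Plot helpers for the descriptive outputs.

Thin matplotlib wrappers; each returns the Figure so callers can save or
embed it.  Nothing here feeds back into the analysis.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .features import NormalizedTable


def density_plot(ntable: NormalizedTable, variables: Sequence[str], bw: float | None = None):
    """Per-class density of selected variables (Gaussian KDE)."""
    from scipy.stats import gaussian_kde

    n = len(variables)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3), squeeze=False)
    classes = sorted(ntable.metadata["isomer"].unique())
    for ax, var in zip(axes[0], variables):
        for cls in classes:
            x = ntable.values.loc[ntable.metadata["isomer"] == cls, var]
            if x.std() > 0:
                grid = np.linspace(x.min(), x.max(), 200)
                ax.plot(grid, gaussian_kde(x, bw_method=bw)(grid), label=cls)
        ax.set_title(var, fontsize=9)
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    return fig


def weekly_profile_plot(profiles: pd.DataFrame, variable: str):
    """Mean +- sd per class over weeks for one variable."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    sub = profiles[profiles["variable"] == variable]
    for cls, grp in sub.groupby("isomer"):
        ax.errorbar(grp["week"], grp["mean"], yerr=grp["sd"], label=cls, capsize=2)
    ax.set_xlabel("week")
    ax.set_ylabel("normalized abundance")
    ax.set_title(variable, fontsize=9)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def correlation_heatmap(corr: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(0.25 * len(corr) + 2,) * 2)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig
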