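"""Forest and weight plots for group index fits."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .results import forest_plot_data, weight_plot_data

__all__ = ["forest_plot", "weight_plot"]


def forest_plot(effects: pd.DataFrame, ax=None, title: str | None = None):
    """Forest plot of odds ratios and 95% intervals with a null line at 1.0."""
    table = forest_plot_data(effects)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    ypos = np.arange(len(table))[::-1]
    finite_hi = np.where(np.isfinite(table["ci_upper"]),
                         table["ci_upper"], table["odds_ratio"])
    ax.errorbar(
        table["odds_ratio"], ypos,
        xerr=[table["odds_ratio"] - table["ci_lower"],
              finite_hi - table["odds_ratio"]],
        fmt="o", color="black", ecolor="black", capsize=3, lw=1)
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["variable"])
    ax.set_xlabel("Odds ratio (95% interval)")
    if title:
        ax.set_title(title)
    ax.figure.tight_layout()
    return ax


def weight_plot(weights: pd.DataFrame, title: str | None = None):
    """Bar plots of estimated chemical weights, one panel per group, with the
    1/C_k importance threshold drawn as a horizontal line."""
    table = weight_plot_data(weights)
    groups = list(dict.fromkeys(table["group"]))
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(7, 2.2 * len(groups)), squeeze=False)
    for ax, g in zip(axes[:, 0], groups):
        sub = table[table["group"] == g]
        ax.bar(sub["chemical"], sub["weight"], color="steelblue")
        ax.axhline(sub["threshold"].iloc[0], color="firebrick",
                   ls="--", lw=1, label="1/C threshold")
        ax.set_ylabel("weight")
        ax.set_title(str(g), fontsize=10)
        ax.tick_params(axis="x", rotation=60, labelsize=8)
        ax.legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
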