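"""Figure-style panels for simulation results.

Each plot shows a performance measure (mean estimate or mean SE of the
treatment effect) against an effect size or missingness proportion, one line
per grouping level, with error bars at 1.96 x Monte Carlo error.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

Z_ERRORBAR = 1.96


def _panel(ax, df: pd.DataFrame, x: str, value: str, err: str, group: str) -> None:
    for level, sub in df.groupby(group):
        sub = sub.sort_values(x)
        ax.errorbar(sub[x], sub[value], yerr=Z_ERRORBAR * sub[err],
                    marker="o", capsize=3, label=f"{group}={level}")
    ax.set_xlabel(x)
    ax.set_ylabel(value)
    ax.legend(fontsize=8)


def plot_effect_grid(df: pd.DataFrame, x: str, group: str, out_path: str | Path,
                     title: str = "") -> Path:
    """Two-row panel (mean estimate on top, mean SE below), columns split by
    interaction absent/present when both occur in the results."""
    df = df.copy()
    df["interaction"] = (df["delta3"] > 0) | (df["delta5"] > 0)
    inter_levels = sorted(df["interaction"].unique())
    fig, axes = plt.subplots(2, len(inter_levels), figsize=(5 * len(inter_levels), 7),
                             squeeze=False)
    for col, inter in enumerate(inter_levels):
        sub = df[df["interaction"] == inter]
        _panel(axes[0][col], sub, x, "mean_beta2", "mc_error_mean", group)
        _panel(axes[1][col], sub, x, "mean_se", "mc_error_se", group)
        axes[0][col].set_title(
            ("with" if inter else "without") + " treatment interaction")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path


def plot_missingness_grid(df: pd.DataFrame, out_path: str | Path) -> Path:
    """Mean estimate and SE vs proportion of missing days, columns by mechanism,
    lines by proportion of affected participants."""
    df = df[df["mechanism"] != "none"]
    mechanisms = sorted(df["mechanism"].unique())
    fig, axes = plt.subplots(2, len(mechanisms), figsize=(5 * len(mechanisms), 7),
                             squeeze=False)
    for col, mech in enumerate(mechanisms):
        sub = df[df["mechanism"] == mech]
        _panel(axes[0][col], sub, "prop_days", "mean_beta2", "mc_error_mean",
               "prop_participants")
        _panel(axes[1][col], sub, "prop_days", "mean_se", "mc_error_se",
               "prop_participants")
        axes[0][col].set_title(mech)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
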