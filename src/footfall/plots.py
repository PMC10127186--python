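"""Basic chart export: Bland–Altman, regression scatters, ICC vs weeks."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .agreement import BlandAltmanResult, RegressionResult

__all__ = ["bland_altman_plot", "regression_plot", "icc_vs_weeks_plot"]


def bland_altman_plot(sensor, manual, result: BlandAltmanResult, path) -> None:
    sensor = np.asarray(sensor, float)
    manual = np.asarray(manual, float)
    means = (sensor + manual) / 2.0
    diffs = sensor - manual
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, color="black", s=18)
    ax.axhline(result.mean_diff, linestyle="--", color="tab:blue",
               label=f"mean diff {result.mean_diff:.2f}")
    for loa in (result.loa_low, result.loa_high):
        ax.axhline(loa, linestyle=":", color="tab:red")
    ax.set_xlabel("Mean of sensor and manual counts per hour")
    ax.set_ylabel("Sensor − manual counts per hour")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def regression_plot(x, y, result: RegressionResult, path,
                    xlabel: str = "x", ylabel: str = "y",
                    unity: bool = False) -> None:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, color="black", s=18)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, result.slope * grid + result.intercept, "--",
            color="tab:blue", label=f"fit (r²={result.r_squared:.2f})")
    if unity:
        ax.plot(grid, grid, "-", color="grey", linewidth=1, label="unity")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def icc_vs_weeks_plot(table, path) -> None:
    """Mean ICC against number of weeks, one line per counter-season."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for (cid, season), sub in table.groupby(["counter_id", "season"]):
        sub = sub.sort_values("k_weeks")
        ax.plot(sub["k_weeks"], sub["mean_icc"], marker="o",
                label=f"{cid} {season}")
    ax.axhline(0.75, linestyle=":", color="grey")
    ax.axhline(0.9, linestyle=":", color="grey")
    ax.set_xlabel("Weeks of monitoring")
    ax.set_ylabel("Mean ICC vs full season")
    ax.legend(loc="lower right", fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
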