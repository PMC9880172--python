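"""Static figure output for the main analysis artifacts.

All functions write a file and return the path; they use the Agg backend
so they work headless.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_km", "plot_forest", "plot_pcvpc"]


def plot_km(km_result: dict, path) -> str:
    """Kaplan-Meier curves per exposure quartile plus control."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for label, kmf in km_result["curves"].items():
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("time (weeks)")
    ax.set_ylabel("progression-free survival")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"log-rank p = {km_result['logrank_p']:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_forest(table: pd.DataFrame, path, ratio_col="hr",
                lo_col="ci_low", hi_col="ci_high", label_col="term",
                reference_band=(0.8, 1.25)) -> str:
    """Horizontal forest plot of ratios with CIs.

    Works for Cox hazard-ratio tables and covariate effect-size tables
    (pass ratio_col='ratio', label_col='scenario')."""
    fig, ax = plt.subplots(figsize=(7, 0.6 * len(table) + 1.5))
    y = np.arange(len(table))[::-1]
    ax.errorbar(
        table[ratio_col], y,
        xerr=[table[ratio_col] - table[lo_col], table[hi_col] - table[ratio_col]],
        fmt="o", color="black", capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=1)
    if reference_band:
        ax.axvspan(*reference_band, color="tab:blue", alpha=0.08)
    ax.set_yticks(y)
    ax.set_yticklabels(table[label_col])
    ax.set_xlabel("ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def plot_pcvpc(table: pd.DataFrame, path) -> str:
    """Observed binned percentiles against their simulated 95% PIs."""
    fig, ax = plt.subplots(figsize=(7, 5))
    mid = 0.5 * (table["tad_low"] + table["tad_high"])
    colors = {"p5": "tab:red", "p50": "tab:blue", "p95": "tab:red"}
    for p, c in colors.items():
        ax.fill_between(mid, table[f"sim_{p}_lo"], table[f"sim_{p}_hi"],
                        color=c, alpha=0.2)
        ax.plot(mid, table[f"obs_{p}"], color=c, marker="o", lw=1.2, label=f"observed {p}")
    ax.set_xlabel("time after previous dose (h)")
    ax.set_ylabel("prediction-corrected concentration (ug/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
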