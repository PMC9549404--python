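"""Diagnostic plots: goodness-of-fit panel, VPC bands, trough distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["plot_gof", "plot_vpc", "plot_trough_distributions"]


def plot_gof(gof, path=None):
    """Four-panel goodness-of-fit plot (DV vs IPRED/PRED, CWRES vs PRED/TAD)."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    lim = max(gof["DV"].max(), gof["IPRED"].max(), gof["PRED"].max()) * 1.05
    for ax, xcol in zip(axes[0], ("IPRED", "PRED")):
        ax.plot(gof[xcol], gof["DV"], "o", ms=4, alpha=0.6)
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(f"{xcol} (mg/L)")
        ax.set_ylabel("DV (mg/L)")
    for ax, xcol in zip(axes[1], ("PRED", "TAD")):
        ax.plot(gof[xcol], gof["CWRES"], "o", ms=4, alpha=0.6)
        for y in (-2, 0, 2):
            ax.axhline(y, color="k", ls="--", lw=0.8)
        ax.set_xlabel(f"{xcol}" + (" (mg/L)" if xcol == "PRED" else " (h)"))
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_vpc(report, path=None):
    """Observed percentiles over simulated confidence bands per TAD bin."""
    fig, ax = plt.subplots(figsize=(8, 5))
    t = report.table["t_mid"]
    colors = {5: "tab:blue", 50: "tab:red", 95: "tab:blue"}
    for p in report.percentiles:
        c = colors.get(p, "tab:gray")
        ax.fill_between(t, report.table[f"lo_p{p:g}"], report.table[f"hi_p{p:g}"],
                        alpha=0.25, color=c)
        ax.plot(t, report.table[f"obs_p{p:g}"], "-o", ms=4, color=c,
                label=f"observed P{p}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("concentration (mg/L)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_trough_distributions(results: dict, path=None):
    """Simulated trough distributions across maintenance doses, one panel
    per (stratum, route) scenario."""
    scenarios = sorted({(k[0], k[1]) for k in results})
    fig, axes = plt.subplots(1, len(scenarios), figsize=(4 * len(scenarios), 4),
                             squeeze=False)
    for ax, (stratum, route) in zip(axes[0], scenarios):
        doses = sorted(k[2] for k in results if k[:2] == (stratum, route))
        data = [results[(stratum, route, d)].troughs for d in doses]
        ax.boxplot(data, tick_labels=[f"{d:g}" for d in doses], showfliers=False)
        for y in results[(stratum, route, doses[0])].thresholds:
            ax.axhline(y, color="r", ls="--", lw=0.8)
        ax.set_title(f"{stratum}, {route}")
        ax.set_xlabel("maintenance dose (mg q12h)")
        ax.set_ylabel("trough (mg/L)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
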