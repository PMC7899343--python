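"""Optional report figures (matplotlib).

Mirrors the standard validation graphics: per-algorithm error bars, the
error-vs-number-of-counters curve, consensus-vs-expert scatter with the 1:1
line, and flight-total comparison. All functions take report tables and
return the matplotlib Figure; ``save_report_figures`` writes them all.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .validation import ValidationReport

__all__ = [
    "plot_error_by_algorithm",
    "plot_error_by_n_counters",
    "plot_cs_vs_expert",
    "plot_flight_totals",
    "save_report_figures",
]


def plot_error_by_algorithm(mean_errors: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(7, 4))
    pivot = mean_errors.pivot(index="algorithm", columns="species", values="mean_rel_error")
    pivot.plot.bar(ax=ax, rot=30)
    ax.set_ylabel("mean relative error")
    ax.set_xlabel("consensus algorithm")
    fig.tight_layout()
    return fig


def plot_error_by_n_counters(error_by_n: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(7, 4))
    for (sp, alg), grp in error_by_n.groupby(["species", "algorithm"]):
        ax.plot(grp["n_counters"], grp["mean_rel_error"], marker="o", ms=3,
                alpha=0.6, label=f"{sp} / {alg}")
    ax.set_xlabel("number of counters")
    ax.set_ylabel("mean relative error")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    return fig


def plot_cs_vs_expert(photo_errors: pd.DataFrame, algorithms: list[str] | None = None):
    df = photo_errors
    if algorithms:
        df = df[df["algorithm"].isin(algorithms)]
    species = sorted(df["species"].unique())
    fig, axes = plt.subplots(1, len(species), figsize=(4.5 * len(species), 4), squeeze=False)
    for ax, sp in zip(axes[0], species):
        sub = df[df["species"] == sp]
        for alg, grp in sub.groupby("algorithm"):
            ax.scatter(grp["expert"], grp["cs"], s=6, alpha=0.4, label=alg)
        lim = max(sub["expert"].max(), sub["cs"].max(), 1)
        ax.plot([0, lim], [0, lim], "k-", lw=1, label="1:1")
        ax.set_title(sp)
        ax.set_xlabel("expert count")
        ax.set_ylabel("consensus count")
        ax.legend(fontsize=6)
    fig.tight_layout()
    return fig


def plot_flight_totals(totals: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(7, 4))
    key = totals["flight_id"] + " / " + totals["species"]
    for alg, grp in totals.groupby("algorithm"):
        ax.scatter(grp["flight_id"] + " / " + grp["species"], grp["total_cs"], label=alg, s=20)
    ax.scatter(key, totals["total_expert"], marker="x", c="k", label="expert", zorder=3)
    ax.set_ylabel("flight total count")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def save_report_figures(report: ValidationReport, out_dir: str | Path, fmt: str = "png") -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    figures = {
        "error_by_algorithm": plot_error_by_algorithm(report.mean_rel_error()),
        "error_by_n_counters": plot_error_by_n_counters(report.error_by_n),
        "cs_vs_expert": plot_cs_vs_expert(report.photo_errors),
        "flight_totals": plot_flight_totals(report.flight_totals),
    }
    written = []
    for name, fig in figures.items():
        p = out / f"{name}.{fmt}"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        written.append(p)
    return written
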