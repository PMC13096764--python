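"""Per-chromosome scan plots (no circos)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_genome_scan(results, path: str | Path | None = None):
    """SNP-index / delta-SNP-index tracks per chromosome with the 95% band."""
    stats = results.window_stats
    chroms = list(stats["CHROM"].unique())
    fig, axes = plt.subplots(len(chroms), 1, squeeze=False,
                             figsize=(9, 2.2 * len(chroms)), sharey=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        win = stats[(stats["CHROM"] == chrom) & (stats["N_SNPS"] > 0)]
        mid = (win["START"] + win["END"]) / 2e6
        if "MEAN_INDEX1" in win.columns:
            ax.plot(mid, win["MEAN_INDEX1"], color="tab:blue", lw=0.8,
                    label="high bulk")
            ax.plot(mid, win["MEAN_INDEX2"], color="black", lw=0.8,
                    label="low bulk")
        ax.plot(mid, win["MEAN_DELTA"], color="tab:red", lw=1.2,
                label="delta")
        if "BAND95" in win.columns:
            ax.fill_between(mid, -win["BAND95"], win["BAND95"],
                            color="grey", alpha=0.25, label="95% null band")
        for iv in results.intervals:
            if iv.chrom == chrom:
                ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="red",
                           alpha=0.12)
        ax.set_ylabel(str(chrom))
        ax.set_ylim(-1, 1)
    axes[0, 0].legend(loc="upper right", fontsize=7, ncol=4)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_refine_trace(trace, path: str | Path | None = None):
    """One panel per ladder rung: retained-window mean delta profiles."""
    rungs = trace.rungs
    if not rungs:
        raise ValueError("empty refinement trace")
    fig, axes = plt.subplots(len(rungs), 1, squeeze=False,
                             figsize=(9, 1.8 * len(rungs)), sharex=True)
    for ax, (spec, stats) in zip(axes[:, 0], rungs):
        if not stats.empty:
            mid = (stats["START"] + stats["END"]) / 2e6
            ax.plot(mid, stats["MEAN_DELTA"], ".", ms=3, color="tab:red")
        ax.set_ylabel(f"{spec.size / 1e3:g}k/{spec.step / 1e3:g}k",
                      fontsize=8)
        ax.set_ylim(-1, 1)
    cand = trace.candidate
    if cand is not None:
        axes[-1, 0].axvspan(cand.start / 1e6, cand.end / 1e6, color="red",
                            alpha=0.15)
    axes[-1, 0].set_xlabel(f"{trace.region.chrom} position (Mb)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_lod_profile(results, path: str | Path | None = None):
    """LOD curves per linkage group with the permutation threshold."""
    table = results.scan.table
    groups = list(table["GROUP"].unique())
    fig, axes = plt.subplots(1, len(groups), squeeze=False,
                             figsize=(4.5 * len(groups), 3), sharey=True)
    for ax, g in zip(axes[0], groups):
        sub = table[table["GROUP"] == g]
        ax.plot(sub["CM"], sub["LOD"], color="black")
        cm = results.gmap.cm[g]
        ax.plot(cm, np.interp(cm, sub["CM"], sub["LOD"]), "D",
                color="tab:red", ms=4)
        if results.threshold is not None:
            ax.axhline(results.threshold, ls="--", color="grey")
        ax.set_xlabel(f"{g} (cM)")
    axes[0][0].set_ylabel("LOD")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
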