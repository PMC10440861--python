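"""Per-sample profile bar charts and breakpoint rainfall plots.

Data assembly is separated from rendering: ``profile_series`` returns
the exact bar heights (the sample's matrix column in canonical channel
order) so tests assert numbers rather than pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .channels import (
    CNV_SIZE_BINS,
    HET_TCN_CLASSES,
    HOMDEL_SIZE_BINS,
    LOH_TCN_CLASSES,
)
from .genome import AUTOSOMES, CHROM_LENGTHS
from .matrix import ChannelMatrix
from .sv import Breakpoint

SV_TYPE_COLORS = {
    "del": "#E41A1C",
    "tds": "#377EB8",
    "inv": "#4DAF4A",
    "trans": "#984EA3",
}

# (group title, member channel count) blocks in canonical CNV48 order.
_CNV_GROUPS = (
    [("0:homdel", len(HOMDEL_SIZE_BINS))]
    + [(f"{t}:LOH", len(CNV_SIZE_BINS)) for t in LOH_TCN_CLASSES]
    + [(f"{t}:het", len(CNV_SIZE_BINS)) for t in HET_TCN_CLASSES]
)
_CNV_GROUP_COLORS = plt.get_cmap("tab10")


def profile_series(matrix: ChannelMatrix, sample: str) -> pd.Series:
    """Bar heights of a sample's profile: its matrix column, canonical order."""
    if sample not in matrix.sample_ids:
        raise KeyError(f"unknown sample: {sample!r}")
    return matrix.column(sample)


def _bar_colors(matrix: ChannelMatrix) -> list[str]:
    if matrix.schema == "cnv48":
        colors = []
        for i, (_, n) in enumerate(_CNV_GROUPS):
            colors += [matplotlib.colors.to_hex(_CNV_GROUP_COLORS(i % 10))] * n
        return colors
    colors = []
    for label in matrix.channel_labels:
        svtype = label.split("_")[1]
        colors.append(SV_TYPE_COLORS[svtype])
    return colors


def plot_profile(
    matrix: ChannelMatrix, sample: str, out: str | Path, format: str = "png"
) -> Path:
    """Render a per-sample channel profile bar chart (PNG or PDF).

    CNV profiles group bars by heterozygosity state and TCN class with
    size bins within each group; SV profiles split clustered from
    non-clustered and color bars by event type.
    """
    if format not in ("png", "pdf"):
        raise ValueError(f"unsupported format: {format!r}")
    heights = profile_series(matrix, sample)
    out = Path(out)
    fig, ax = plt.subplots(figsize=(14, 4.5))
    x = np.arange(len(heights))
    ax.bar(x, heights.to_numpy(), color=_bar_colors(matrix), width=0.8)
    ax.set_xticks(x)
    ax.set_ylabel("Count")
    ax.set_title(sample)
    ax.set_xlim(-0.8, len(heights) - 0.2)
    top = max(1, int(heights.max()))
    ax.set_ylim(0, top * 1.25)

    if matrix.schema == "cnv48":
        sizes = list(HOMDEL_SIZE_BINS) + list(CNV_SIZE_BINS) * 9
        ax.set_xticklabels(sizes, rotation=90, fontsize=6)
        ax.set_xlabel("Segment size")
        edge = 0
        for title, n in _CNV_GROUPS:
            ax.text((edge + edge + n - 1) / 2, top * 1.12, title,
                    ha="center", fontsize=7)
            edge += n
            if edge < len(heights):
                ax.axvline(edge - 0.5, color="0.8", lw=0.8)
    else:
        labels = []
        for label in matrix.channel_labels:
            parts = label.split("_")
            labels.append(parts[2] if len(parts) == 3 else "trans")
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_xlabel("Event size")
        half = len(heights) // 2
        ax.axvline(half - 0.5, color="0.3", lw=1.2)
        ax.text(half / 2 - 0.5, top * 1.12, "clustered", ha="center", fontsize=9)
        ax.text(half + half / 2 - 0.5, top * 1.12, "non-clustered",
                ha="center", fontsize=9)
        handles = [plt.Rectangle((0, 0), 1, 1, color=c)
                   for c in SV_TYPE_COLORS.values()]
        ax.legend(handles, SV_TYPE_COLORS.keys(), fontsize=7, ncol=4,
                  loc="upper right", frameon=False)

    fig.tight_layout()
    fig.savefig(out, format=format, dpi=150)
    plt.close(fig)
    if not out.exists() or out.stat().st_size == 0:
        raise OSError(f"failed to write plot: {out}")
    return out


def plot_rainfall(
    breakpoints: list[Breakpoint], out: str | Path, format: str = "png",
    title: str | None = None,
) -> Path:
    """Rainfall plot: breakpoint coordinate vs log10 IMD, colored by SV type.

    Chromosomes are concatenated on the x axis in karyotype order with
    separators; clustered breakpoints are drawn with a black edge.
    """
    if format not in ("png", "pdf"):
        raise ValueError(f"unsupported format: {format!r}")
    out = Path(out)
    order = list(AUTOSOMES) + ["X", "Y"]
    offsets = {}
    off = 0
    for chrom in order:
        offsets[chrom] = off
        off += CHROM_LENGTHS[chrom]
    fig, ax = plt.subplots(figsize=(14, 4))
    for bp in breakpoints:
        if np.isnan(bp.imd):
            continue
        ax.scatter(
            offsets[bp.chromosome] + bp.position,
            np.log10(bp.imd + 1.0),
            s=14,
            color=SV_TYPE_COLORS[bp.parent.svclass],
            edgecolors="black" if bp.clustered else "none",
            linewidths=0.6,
        )
    for chrom in order:
        ax.axvline(offsets[chrom], color="0.9", lw=0.6)
    ax.set_xticks([offsets[c] + CHROM_LENGTHS[c] / 2 for c in order])
    ax.set_xticklabels(order, fontsize=7)
    ax.set_xlim(0, off)
    ax.set_xlabel("Genomic position")
    ax.set_ylabel("log10 inter-mutational distance")
    if title:
        ax.set_title(title)
    handles = [plt.Line2D([], [], marker="o", ls="", color=c)
               for c in SV_TYPE_COLORS.values()]
    ax.legend(handles, SV_TYPE_COLORS.keys(), fontsize=7, ncol=4,
              loc="upper right", frameon=False)
    fig.tight_layout()
    fig.savefig(out, format=format, dpi=150)
    plt.close(fig)
    return out
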