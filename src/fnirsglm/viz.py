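"""Simple 2-D summaries: ROI t-value bars and a channel t-map grid."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .montage import Montage

__all__ = ["plot_roi_bars", "plot_channel_grid"]


def plot_roi_bars(roi_stats: pd.DataFrame, path: str | Path, alpha: float = 0.05):
    """Grouped bar chart of ROI t-values per contrast; significant bars solid."""
    contrasts = list(pd.unique(roi_stats["contrast"]))
    rois = list(pd.unique(roi_stats["roi"]))
    width = 0.8 / max(len(contrasts), 1)
    fig, ax = plt.subplots(figsize=(1.6 * len(rois) + 2, 4))
    for i, contrast in enumerate(contrasts):
        sub = roi_stats[roi_stats["contrast"] == contrast].set_index("roi")
        xs = np.arange(len(rois)) + (i - (len(contrasts) - 1) / 2) * width
        tvals = sub.reindex(rois)["t"]
        sig = sub.reindex(rois)["p_fdr"] < alpha
        ax.bar(xs, tvals, width=width, label=contrast,
               alpha=1.0, edgecolor="black",
               hatch=["" if s else "//" for s in sig][0] if len(sig) else "")
        for x, t, s in zip(xs, tvals, sig):
            if not s and np.isfinite(t):
                ax.bar([x], [t], width=width, color="white", edgecolor="gray", hatch="//")
    ax.set_xticks(np.arange(len(rois)))
    ax.set_xticklabels(rois)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("t-value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_channel_grid(
    channel_stats: pd.DataFrame,
    montage: Montage,
    path: str | Path,
    alpha: float = 0.05,
):
    """Channels at their MNI x/y positions, colored by t, one panel per contrast."""
    contrasts = list(pd.unique(channel_stats["contrast"]))
    fig, axes = plt.subplots(1, len(contrasts), figsize=(4 * len(contrasts), 4),
                             squeeze=False)
    pos = {ch.name: (ch.mni[0], ch.mni[1]) for ch in montage.channels}
    vmax = float(np.nanmax(np.abs(channel_stats["t"]))) or 1.0
    for ax, contrast in zip(axes[0], contrasts):
        sub = channel_stats[channel_stats["contrast"] == contrast]
        xs = [pos[c][0] for c in sub["channel"]]
        ys = [pos[c][1] for c in sub["channel"]]
        sc = ax.scatter(xs, ys, c=sub["t"], cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                        s=120, edgecolors=np.where(sub["p_fdr"] < alpha, "black", "none"))
        ax.set_title(contrast, fontsize=9)
        ax.set_xlabel("MNI x (mm)")
        ax.set_ylabel("MNI y (mm)")
    fig.colorbar(sc, ax=axes[0].tolist(), label="t-value", shrink=0.8)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
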