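"""Figure export for screening results (volcano, heatmap, score plots).

Every figure is regenerable from its delimited table alone; plotting never
recomputes statistics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["volcano_plot", "heatmap_plot", "score_plot"]


def volcano_plot(volcano: pd.DataFrame, path: str | Path, p_threshold: float = 0.05,
                 title: str = "") -> Path:
    """log2 fold change vs -log10 p with the raw-p threshold line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano["significant"].to_numpy(dtype=bool)
    ax.scatter(volcano.loc[~sig, "log2_fc"], volcano.loc[~sig, "neg_log10_p"],
               s=12, c="grey", alpha=0.6, label="n.s.")
    ax.scatter(volcano.loc[sig, "log2_fc"], volcano.loc[sig, "neg_log10_p"],
               s=14, c="crimson", label=f"p < {p_threshold:g}")
    ax.axhline(-np.log10(p_threshold), ls="--", c="black", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p-value")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def heatmap_plot(heat: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Lipids x comparisons heatmap of -log10 p-values."""
    fig, ax = plt.subplots(figsize=(2 + 0.6 * heat.shape[1], 1 + 0.16 * heat.shape[0]))
    im = ax.imshow(heat.to_numpy(dtype=float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(heat.shape[1]), heat.columns, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(heat.shape[0]), heat.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="-log10 p")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def score_plot(scores: pd.DataFrame, labels: pd.Series, path: str | Path,
               title: str = "") -> Path:
    """First-two-component score scatter colored by group label."""
    fig, ax = plt.subplots(figsize=(5, 4))
    cols = scores.columns[:2]
    for group in pd.unique(labels):
        mask = (labels == group).to_numpy()
        ax.scatter(scores.loc[mask, cols[0]], scores.loc[mask, cols[1]], s=18, label=str(group))
    ax.set_xlabel(str(cols[0]))
    ax.set_ylabel(str(cols[1]) if len(cols) > 1 else "")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
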