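"""Standard figures: distance heatmap, scree, loading rank and density plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def distance_heatmap(dist: pd.DataFrame, group_labels: dict[str, str] | None = None, path=None):
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(dist.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(dist)), dist.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(dist)), dist.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="euclidean distance")
    ax.set_title("Pairwise methylation distance")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def scree_plot(explained_variance_ratio: np.ndarray, path=None):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(1, len(explained_variance_ratio) + 1)
    ax.bar(x, 100 * explained_variance_ratio)
    ax.set_xlabel("component")
    ax.set_ylabel("% variance explained")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def loading_rank_plot(ranked: pd.Series, selected=None, path=None, title: str = ""):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(len(ranked)), ranked.to_numpy(), ".", ms=2, color="gray")
    if selected is not None:
        pos = {p: i for i, p in enumerate(ranked.index)}
        idx = [pos[p] for p in selected.index if p in pos]
        ax.plot(idx, ranked.iloc[idx].to_numpy(), ".", ms=3, color="crimson", label="selected")
        ax.legend()
    ax.set_xlabel("rank")
    ax.set_ylabel("loading")
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def density_plot(profiles: pd.DataFrame, group_labels: dict[str, str] | None = None, path=None):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    groups = sorted({(group_labels or {}).get(s, "unknown") for s in profiles.columns})
    cmap = plt.get_cmap("tab10")
    color = {g: cmap(i % 10) for i, g in enumerate(groups)}
    for s in profiles.columns:
        g = (group_labels or {}).get(s, "unknown")
        ax.plot(profiles.index, profiles[s], color=color[g], lw=0.8)
    ax.set_xlabel("beta value")
    ax.set_ylabel("density")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
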