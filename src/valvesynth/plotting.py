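"""Thin matplotlib layer for the standard inspection figures."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def save_exploration_grid(grid: np.ndarray, dims: list[int], path: str | Path) -> None:
    """Latent exploration panel: rows = latent dimensions, cols = offsets."""
    n_dims, n_offsets = grid.shape[:2]
    fig, axes = plt.subplots(n_dims, n_offsets,
                             figsize=(1.1 * n_offsets, 2.0 * n_dims), squeeze=False)
    for i in range(n_dims):
        for j in range(n_offsets):
            ax = axes[i][j]
            ax.imshow(grid[i, j], cmap="gray", vmin=0, vmax=1)
            ax.set_xticks([]), ax.set_yticks([])
        axes[i][0].set_ylabel(f"z[{dims[i]}]")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def save_distribution_violins(features, path: str | Path) -> None:
    """Violin plots of length/width/area per leaflet type and source."""
    import seaborn as sns

    feat_cols = [c for c in ("length", "width", "area") if c in features.columns]
    fig, axes = plt.subplots(1, len(feat_cols), figsize=(4 * len(feat_cols), 4))
    axes = np.atleast_1d(axes)
    for ax, col in zip(axes, feat_cols):
        sns.violinplot(data=features, x="leaflet_type", y=col, hue="source",
                       cut=0, ax=ax)
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def save_tsne_scatter(coords: np.ndarray, labels: list[str], path: str | Path) -> None:
    """2D embedding scatter colored by leaflet type."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        ax.scatter(coords[idx, 0], coords[idx, 1], label=lab, s=18, alpha=0.8)
    ax.legend()
    ax.set_xlabel("t-SNE 1"), ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
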