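"""Plot helpers (t-SNE scatter, rank-score heatmap); all optional output."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_tsne", "plot_heatmap"]


def plot_tsne(coords: np.ndarray, labels: pd.Series, path) -> None:
    """Scatter the 2-D embedding coloured by a categorical label."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for value in dict.fromkeys(labels):
        mask = (labels == value).to_numpy()
        ax.scatter(coords[mask, 0], coords[mask, 1], s=6, label=str(value), alpha=0.7)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(markerscale=2, fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(values: pd.DataFrame, path, cmap: str = "RdBu_r") -> None:
    """Gene x group heatmap of rank scores or expressions."""
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * values.shape[1] + 2), max(4, 0.12 * len(values))))
    vmax = np.nanmax(np.abs(values.to_numpy())) or 1.0
    im = ax.imshow(values.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(values.shape[1]), labels=[str(c) for c in values.columns], rotation=90)
    ax.set_yticks(range(len(values)), labels=values.index, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
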