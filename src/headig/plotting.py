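"""Figure export: head-grid heatmaps, map-embedding scatter, drop curves."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cluster import MapEmbedding
from .faithfulness import SubstitutionResult
from .stats import HeadStatMatrix


def plot_head_grid(matrix: HeadStatMatrix, path: str | Path,
                   title: str = "") -> None:
    """Heatmap of an n_layers x n_heads grid; NaN cells are hatched grey."""
    fig, ax = plt.subplots(figsize=(1.2 + 0.6 * matrix.shape[1],
                                    1.0 + 0.5 * matrix.shape[0]))
    masked = np.ma.masked_invalid(matrix.values)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgrey")
    im = ax.imshow(masked, aspect="auto", cmap=cmap)
    ax.set_xlabel("head")
    ax.set_ylabel("layer")
    ax.set_title(title or matrix.content_kind)
    fig.colorbar(im, ax=ax, label=matrix.content_kind)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_map_embedding(embedding: MapEmbedding, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4.5))
    labels = np.asarray(embedding.labels)
    for lab in np.unique(labels):
        pts = embedding.coordinates[labels == lab]
        ax.scatter(pts[:, 0], pts[:, 1], s=14, label=str(lab), alpha=0.8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(title="class", fontsize=8)
    ax.set_title("summed attribution maps, PCA + t-SNE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_substitution_curves(results: Sequence[SubstitutionResult],
                             path: str | Path) -> None:
    """Mean drop curves over sequences, relevance-ordered vs random."""
    k = results[0].k_values
    rel = np.mean([r.drop_by_relevance for r in results], axis=0)
    rnd = np.mean([r.drop_random for r in results], axis=0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(k, rel, "o-", label="by relevance")
    ax.plot(k, rnd, "s--", label="random")
    ax.set_xlabel("residues substituted (k)")
    ax.set_ylabel("class-probability drop")
    ax.legend()
    ax.set_title(f"substitution test (n={len(results)} sequences)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
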