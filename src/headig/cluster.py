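"""Collective-dynamics view of summed attribution maps.

Each protein's n_layers x n_heads summed attribution map is flattened to a
vector (losing all reference to sequence positions — the structure that
remains is purely the relevance distribution over heads), reduced with PCA,
embedded in 2-D with t-SNE, and the class structure of the embedding is
quantified with the silhouette score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

__all__ = ["MapEmbedding", "flatten_maps", "unflatten_map", "embed_2d",
           "cluster_separation"]

# pinned "default" t-SNE parameters ("default" drifts across library versions)
TSNE_PERPLEXITY = 30.0
TSNE_LEARNING_RATE = "auto"


@dataclass
class MapEmbedding:
    """2-D t-SNE coordinates of per-protein summed attribution maps."""

    protein_ids: list[str]
    coordinates: np.ndarray          # (n_proteins, 2)
    labels: list[str]
    pca_dims: int
    seed: int
    pca_coordinates: np.ndarray | None = None   # (n_proteins, pca_dims)

    def __post_init__(self) -> None:
        if self.coordinates.shape != (len(self.protein_ids), 2):
            raise ValueError("one 2-D point per protein required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")


def flatten_maps(
    summed_maps: Sequence[np.ndarray], protein_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Row-major flattening of per-protein (n_layers, n_heads) grids.

    Feature order is fixed: index l * n_heads + h holds (layer l, head h).
    """
    arrs = [np.asarray(m, dtype=np.float64) for m in summed_maps]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"mismatched grid shapes: {sorted(shapes)}")
    if arrs[0].ndim != 2:
        raise ValueError("expected 2-D (n_layers, n_heads) grids")
    return np.stack([a.reshape(-1) for a in arrs])


def unflatten_map(vector: np.ndarray, n_layers: int, n_heads: int) -> np.ndarray:
    return np.asarray(vector).reshape(n_layers, n_heads)


def embed_2d(
    flattened: np.ndarray,
    labels: Sequence[str],
    protein_ids: Sequence[str] | None = None,
    pca_dims: int = 50,
    seed: int = 0,
) -> MapEmbedding:
    """PCA to ``pca_dims`` (capped at what the data supports), then t-SNE to 2-D.

    Deterministic given the seed; t-SNE perplexity is additionally capped to
    remain below the sample count.
    """
    X = np.asarray(flattened, dtype=np.float64)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 proteins to embed")
    if len(labels) != n:
        raise ValueError("one label per protein required")
    if np.allclose(X, X[0]):
        raise ValueError("all summed maps are identical; embedding is degenerate")
    ids = list(protein_ids) if protein_ids is not None else [f"P{i}" for i in range(n)]
    cap = min(n - 1, p)
    if pca_dims > cap:
        warnings.warn(f"pca_dims={pca_dims} capped to {cap} (n={n}, features={p})")
        pca_dims = cap
    Xp = PCA(n_components=pca_dims, random_state=seed).fit_transform(X)
    perplexity = min(TSNE_PERPLEXITY, (n - 1) / 3.0)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=TSNE_LEARNING_RATE,
        init="pca",
        random_state=seed,
    ).fit_transform(Xp)
    return MapEmbedding(ids, np.asarray(coords, dtype=np.float64), list(labels),
                        pca_dims, seed, pca_coordinates=Xp)


def cluster_separation(embedding: MapEmbedding, space: str = "2d") -> float:
    """Silhouette score of the class labels in the embedding.

    ``space='2d'`` scores the t-SNE plane (what the scatter plot shows);
    ``space='pca'`` scores the PCA space before t-SNE.
    """
    labels = np.asarray(embedding.labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("silhouette needs at least 2 classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 points")
    if space == "2d":
        X = embedding.coordinates
    elif space == "pca":
        if embedding.pca_coordinates is None:
            raise ValueError("PCA coordinates were not retained")
        X = embedding.pca_coordinates
    else:
        raise ValueError(f"unknown space {space!r}")
    return float(silhouette_score(X, labels))
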