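"""2D projection of pocket embeddings and binned label-entropy maps.

128-dimensional pocket embedding vectors are projected to two dimensions
with tSNE (default; perplexity 50, 5000 iterations, random initialization,
automatic learning rate), UMAP (min_dist 0), PCA, or ICA.  Over the
projection a regular grid is laid out and, per grid cell, the Shannon
entropy S = −Σ p_i ln p_i of the label distribution (kingdom or species) is
computed, where p_i is the fractional frequency of pockets with label i
among the pockets falling in that cell.  S is reported in nats; 0 ≤ S ≤
ln N for N label categories, with S = 0 meaning a single-label cell and
S = ln N a uniformly mixed one.  Cells with fewer pockets than ``min_count``
(default 20) are masked: no robust entropy estimate exists there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import EmbeddingSet

TSNE_DEFAULTS = {
    "perplexity": 50,
    "max_iter": 5000,
    "learning_rate": "auto",
    "init": "random",
}
UMAP_DEFAULTS = {"n_neighbors": 50, "min_dist": 0.0}


@dataclass
class Projection2D:
    method: str
    params: dict
    coords: np.ndarray  # (n, 2)
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("projection coordinates must be (n, 2)")


def project(
    emb: EmbeddingSet, method: str = "tsne", params: dict | None = None, seed: int = 0
) -> Projection2D:
    """Project the embedding matrix to 2D coordinates.

    ``params`` override the pinned per-method defaults.  For tSNE the
    perplexity must be smaller than the number of pockets.
    """
    x = emb.vectors
    if x.shape[0] < 2:
        raise ValueError("need at least 2 pockets to project")
    method = method.lower()
    params = dict(params or {})
    if method == "tsne":
        from sklearn.manifold import TSNE

        merged = {**TSNE_DEFAULTS, **params}
        if merged["perplexity"] >= x.shape[0]:
            raise ValueError(
                f"perplexity {merged['perplexity']} must be < n_pockets {x.shape[0]}"
            )
        coords = TSNE(n_components=2, random_state=seed, **merged).fit_transform(x)
    elif method == "umap":
        import umap

        merged = {**UMAP_DEFAULTS, **params}
        coords = umap.UMAP(n_components=2, random_state=seed, **merged).fit_transform(x)
        merged = {k: v for k, v in merged.items()}
    elif method == "pca":
        from sklearn.decomposition import PCA

        merged = params
        coords = PCA(n_components=2, random_state=seed, **params).fit_transform(x)
    elif method == "ica":
        from sklearn.decomposition import FastICA

        merged = params
        coords = FastICA(n_components=2, random_state=seed, **params).fit_transform(x)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return Projection2D(method=method, params=merged, coords=np.asarray(coords), seed=seed)


@dataclass
class EntropyGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny) pockets per cell
    entropy: np.ndarray  # (nx, ny), nan where masked
    min_count: int
    label_kind: str
    n_categories: int

    @property
    def max_entropy(self) -> float:
        return float(np.log(self.n_categories))

    @property
    def n_masked(self) -> int:
        return int(np.isnan(self.entropy).sum())


def shannon_entropy(fractions: np.ndarray) -> float:
    """S = −Σ p ln p in nats; absent categories (p = 0) contribute 0."""
    p = np.asarray(fractions, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) + 0.0  # normalize -0.0


def binned_entropy(
    proj: Projection2D,
    labels: "np.ndarray | list[str]",
    n_bins_x: int = 50,
    n_bins_y: int = 50,
    min_count: int = 20,
    label_kind: str = "kingdom",
) -> EntropyGrid:
    """Per-cell Shannon entropy of the label distribution on a regular grid.

    The grid spans the bounding box of the projection.  The category set is
    the set of distinct labels in the whole dataset, so an unmasked cell
    obeys 0 ≤ S ≤ ln N.  Cells with fewer than ``min_count`` pockets are
    masked (NaN entropy).
    """
    if n_bins_x < 1 or n_bins_y < 1:
        raise ValueError("need at least one bin per axis")
    labels = np.asarray(labels)
    if labels.shape[0] != proj.coords.shape[0]:
        raise ValueError("labels must be aligned with the projection")
    categories, label_idx = np.unique(labels, return_inverse=True)
    x, y = proj.coords[:, 0], proj.coords[:, 1]
    x_edges = np.linspace(x.min(), x.max(), n_bins_x + 1)
    y_edges = np.linspace(y.min(), y.max(), n_bins_y + 1)
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, n_bins_x - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, n_bins_y - 1)
    counts = np.zeros((n_bins_x, n_bins_y), dtype=int)
    per_label = np.zeros((n_bins_x, n_bins_y, len(categories)), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    np.add.at(per_label, (ix, iy, label_idx), 1)
    entropy = np.full((n_bins_x, n_bins_y), np.nan)
    occupied = counts >= min_count
    for i, j in zip(*np.nonzero(occupied)):
        entropy[i, j] = shannon_entropy(per_label[i, j] / counts[i, j])
    return EntropyGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        entropy=entropy,
        min_count=min_count,
        label_kind=label_kind,
        n_categories=len(categories),
    )


def plot_entropy_grid(grid: EntropyGrid, path: str, title: str | None = None) -> None:
    """Static heatmap of the entropy grid; masked cells are drawn black."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    shown = np.ma.masked_invalid(grid.entropy.T)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    im = ax.pcolormesh(grid.x_edges, grid.y_edges, shown, cmap=cmap, vmin=0.0)
    fig.colorbar(im, ax=ax, label="entropy S (nats)")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
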