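"""Resolution-scan clustering with silhouette selection and marker-based annotation.

Clustering is a k-means scan over a PCA embedding of the normalized layer; the
number of clusters is chosen by mean silhouette width, the same internal
validity index used to assess cluster separation quality.  Cell types are
assigned per cluster by a specificity-weighted marker z-score, and fine types
can be merged into broad categories (e.g. all neuronal subclusters into one
"Neurons" group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy import sparse
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """Positive (and optional negative) marker genes per cell type; symbols uppercase."""

    positive: dict  # cell type -> list of genes
    negative: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.positive:
            raise ValueError("MarkerSet needs at least one cell type")
        for ct, genes in self.positive.items():
            if not genes:
                raise ValueError(f"empty positive marker list for {ct!r}")
        self.positive = {ct: [g.upper() for g in genes] for ct, genes in self.positive.items()}
        self.negative = {ct: [g.upper() for g in genes] for ct, genes in self.negative.items()}

    def gene_weights(self) -> dict:
        """Specificity weight 1/(number of cell types listing the gene)."""
        counts: dict = {}
        for genes in self.positive.values():
            for g in set(genes):
                counts[g] = counts.get(g, 0) + 1
        for genes in self.negative.values():
            for g in set(genes):
                counts.setdefault(g, counts.get(g, 0))
        return {g: 1.0 / max(c, 1) for g, c in counts.items()}


@dataclass
class ClusteringResult:
    labels: pd.Series            # per-cell cluster label (string)
    silhouette_by_k: dict        # candidate k -> mean silhouette width
    chosen_k: int
    embedding: np.ndarray        # cells x n_pcs PCA coordinates


def silhouette_width(embedding: np.ndarray, labels) -> float:
    """Mean silhouette width s(i) = (b - a) / max(a, b) with Euclidean distances.

    a is the mean distance to other members of the point's own cluster, b the
    minimum over other clusters of the mean distance to that cluster.  Cells in
    singleton clusters score 0.
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("silhouette_width requires >= 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    sizes = np.bincount(inv)
    # mean distance from each point to each cluster
    sums = np.zeros((n, len(uniq)))
    for c in range(len(uniq)):
        sums[:, c] = D[:, inv == c].sum(axis=1)
    s = np.zeros(n)
    for i in range(n):
        c = inv[i]
        if sizes[c] == 1:
            continue  # singleton: s = 0
        a = sums[i, c] / (sizes[c] - 1)
        b = np.inf
        for c2 in range(len(uniq)):
            if c2 != c:
                b = min(b, sums[i, c2] / sizes[c2])
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0  # coincident points
    return float(s.mean())


def _embedding_matrix(data: ad.AnnData, layer: str = "lognorm") -> np.ndarray:
    if layer not in data.layers:
        raise ValueError(f"normalized layer {layer!r} missing; run normalize() first")
    X = data.layers[layer]
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def reduce_and_cluster(
    data: ad.AnnData,
    n_pcs: int = 20,
    k_candidates=(2, 3, 4, 5, 6),
    seed: int = 0,
    layer: str = "lognorm",
) -> ClusteringResult:
    """PCA on the normalized layer, k-means for each candidate k, argmax-silhouette choice.

    Ties in mean silhouette go to the smaller k.  Deterministic under a fixed seed.
    """
    X = _embedding_matrix(data, layer)
    if n_pcs >= min(X.shape):
        raise ValueError("n_pcs must be < min(n_cells, n_genes)")
    k_candidates = sorted(set(int(k) for k in k_candidates))
    for k in k_candidates:
        if not 2 <= k <= X.shape[0] - 1:
            raise ValueError(f"k={k} out of range [2, n_cells-1]")
    emb = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X)
    sil, labelings = {}, {}
    for k in k_candidates:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(emb)
        labelings[k] = km.labels_
        sil[k] = silhouette_width(emb, km.labels_)
    chosen = max(k_candidates, key=lambda k: (sil[k], -k))
    labels = pd.Series([f"c{l}" for l in labelings[chosen]], index=data.obs_names,
                       name="cluster")
    return ClusteringResult(labels=labels, silhouette_by_k=sil, chosen_k=chosen,
                            embedding=emb)


def annotate_clusters(
    data: ad.AnnData,
    labels: pd.Series,
    markers: MarkerSet,
    layer: str = "lognorm",
    z_clip: float = 10.0,
) -> dict:
    """Assign each cluster the cell type with the highest specificity-weighted z-score.

    Per cell, score(type) = sum over positive markers of w_g * z_g minus the
    same sum over negative markers, with z_g the gene-wise z-score of normalized
    expression across cells (clipped to +-z_clip) and w_g = 1 / (number of cell
    types listing g).  Cluster scores are means over member cells; ties give
    "Unknown".
    """
    X = _embedding_matrix(data, layer)
    gene_pos = {g.upper(): i for i, g in enumerate(data.var_names)}
    weights = markers.gene_weights()
    present = [g for g in weights if g in gene_pos]
    if not present:
        raise ValueError("no marker gene present in the dataset")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -z_clip, z_clip)

    cell_scores = {}
    for ct in markers.positive:
        score = np.zeros(X.shape[0])
        for g in markers.positive[ct]:
            if g in gene_pos:
                score += weights[g] * Z[:, gene_pos[g]]
        for g in markers.negative.get(ct, []):
            if g in gene_pos:
                score -= weights[g] * Z[:, gene_pos[g]]
        cell_scores[ct] = score
    score_df = pd.DataFrame(cell_scores, index=data.obs_names)

    labels = pd.Series(labels, index=data.obs_names)
    mapping = {}
    for cl, members in labels.groupby(labels):
        means = score_df.loc[members.index].mean(axis=0)
        best = means.max()
        winners = sorted(means.index[means == best])
        mapping[cl] = winners[0] if len(winners) == 1 else "Unknown"
    return mapping


def merge_celltypes(labels: pd.Series, merge_map: dict) -> pd.Series:
    """Replace fine labels by broad ones; unmapped labels pass through with a warning."""
    labels = pd.Series(labels)
    unmapped = sorted(set(labels.unique()) - set(merge_map))
    if unmapped:
        log.warning("merge_celltypes: unmapped labels pass through: %s", unmapped)
    return labels.map(lambda l: merge_map.get(l, l))
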