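"""Accuracy/dispersion metrics and consensus-clustering surrogate ground truth.

When a dataset ships no cell-type annotation, a surrogate is derived from the
principle that cells of one biological type co-cluster across clustering
resolutions: cluster at a sweep of resolutions, record for every pair of cells
the fraction of runs in which they share a cluster (the consensus matrix), and
cut an average-linkage dendrogram of 1 - consensus into blocks.  The clusterer
is pluggable — any callable mapping (matrix, resolution) -> labels; a Leiden
community-detection default on a kNN expression graph is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix
from .marker_expansion import normalize_expression

__all__ = [
    "ConsensusMatrix",
    "accuracy",
    "per_type_accuracy",
    "index_of_dispersion",
    "consensus_matrix",
    "extract_consensus_blocks",
    "leiden_clusterer",
    "consensus_ground_truth",
    "DEFAULT_RESOLUTIONS",
]

DEFAULT_RESOLUTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


@dataclass
class ConsensusMatrix:
    """Pairwise co-clustering frequencies in [0, 1]."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.cell_ids)
        if self.values.shape != (n, n):
            raise ValueError("consensus matrix must be square over cell_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("consensus values must lie in [0, 1]")


def _align(predicted, truth) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(predicted, pd.Series) and isinstance(truth, pd.Series):
        common = predicted.index.intersection(truth.index)
        if len(common) == 0:
            raise ValueError("no shared spot ids between prediction and truth")
        if len(common) < len(predicted) or len(common) < len(truth):
            raise ValueError("prediction and truth spot ids do not match")
        return (
            predicted.loc[common].to_numpy(),
            truth.loc[common].to_numpy(),
        )
    p = np.asarray(list(predicted))
    t = np.asarray(list(truth))
    if p.size != t.size:
        raise ValueError("prediction and truth lengths differ")
    if p.size == 0:
        raise ValueError("empty label vectors")
    return p, t


def accuracy(predicted, truth) -> float:
    """Fraction of spots whose predicted label equals the ground truth.

    Labels are matched by name (no Hungarian matching); pandas Series inputs
    are aligned on their spot-id index.
    """
    p, t = _align(predicted, truth)
    return float(np.mean(p == t))


def per_type_accuracy(predicted, truth) -> pd.Series:
    """Accuracy restricted to the spots of each true type."""
    p, t = _align(predicted, truth)
    out = {}
    for label in sorted(set(t)):
        sel = t == label
        out[label] = float(np.mean(p[sel] == t[sel]))
    return pd.Series(out, name="accuracy")


def index_of_dispersion(values: Sequence[float]) -> float:
    """Variance-to-mean ratio (sample variance, ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("index of dispersion requires a positive mean")
    return float(v.var(ddof=1) / mean)


def consensus_matrix(
    clusterings: Sequence[Sequence], cell_ids: list[str] | None = None
) -> ConsensusMatrix:
    """Fraction of clusterings in which each pair of cells co-clusters."""
    if len(clusterings) == 0:
        raise ValueError("need at least one clustering")
    arrs = [np.asarray(c) for c in clusterings]
    n = arrs[0].size
    for a in arrs:
        if a.size != n:
            raise ValueError("clusterings must have equal length")
    acc = np.zeros((n, n))
    for a in arrs:
        acc += a[:, None] == a[None, :]
    cell_ids = cell_ids or [f"cell{i + 1}" for i in range(n)]
    return ConsensusMatrix(acc / len(arrs), cell_ids)


def extract_consensus_blocks(cm: ConsensusMatrix, n_blocks: int) -> np.ndarray:
    """Cut an average-linkage dendrogram of 1 - consensus into n_blocks labels."""
    n = len(cm.cell_ids)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_blocks > n:
        raise ValueError("more blocks than cells")
    dist = 1.0 - cm.values
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=n_blocks, criterion="maxclust")


def leiden_clusterer(
    matrix: ExpressionMatrix,
    resolution: float,
    n_neighbors: int = 15,
    n_pcs: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Default resolution-parameterised clusterer: Leiden on a kNN graph.

    Spots are embedded by PCA of normalized log1p expression, connected to
    their nearest neighbours, and partitioned with the RB-configuration
    quality function whose resolution plays the same role as in the usual
    single-cell clustering workflows.
    """
    import igraph as ig
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph

    work = normalize_expression(matrix)
    x = work.values.T  # spots x genes
    n_comp = min(n_pcs, x.shape[0] - 1, x.shape[1])
    emb = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    k = min(n_neighbors, x.shape[0] - 1)
    adj = kneighbors_graph(emb, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    g = ig.Graph(
        n=x.shape[0],
        edges=list(zip(adj.row.tolist(), adj.col.tolist())),
        directed=False,
    ).simplify()
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def consensus_ground_truth(
    matrix: ExpressionMatrix,
    n_blocks: int,
    resolutions: Sequence[float] = DEFAULT_RESOLUTIONS,
    clusterer: Callable[[ExpressionMatrix, float], np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, ConsensusMatrix]:
    """Resolution sweep -> consensus matrix -> block labels (surrogate truth)."""
    if clusterer is None:
        def clusterer(m, r):
            return leiden_clusterer(m, r, seed=seed)
    runs = [np.asarray(clusterer(matrix, float(r))) for r in resolutions]
    cm = consensus_matrix(runs, cell_ids=list(matrix.spot_ids))
    return extract_consensus_blocks(cm, n_blocks), cm
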