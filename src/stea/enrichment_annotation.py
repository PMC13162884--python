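"""Rank-based enrichment scoring per spot and argmax cell-type annotation.

For one spot, genes are ranked (higher rank = higher expression), ordered
descending into a permutation pi, and weighted w_j = R_{pi(j)}^alpha.  Two
cumulative distributions are walked down the ordered list:

    P+(j) = sum_{k<=j} w_k 1[pi(k) in S] / sum_k w_k 1[pi(k) in S]
    P-(j) = sum_{k<=j} 1[pi(k) not in S] / (N - |S|)

and the enrichment score is their mean pointwise difference,

    ES(S) = (1/N) sum_j P+(j) - P-(j),

i.e. the average area between the weighted in-set CDF and the uniform
background CDF.  Unlike classical GSEA's running-sum maximum deviation, the
score integrates over the whole list; alpha (default 0.25) controls how
strongly top-ranked genes dominate.  A spot's major cell type is the gene set
with the maximal score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import (
    AnnotationResult,
    ExpressionMatrix,
    GeneSetCollection,
    match_genes,
)
from .marker_expansion import normalize_expression

logger = logging.getLogger("stea")

__all__ = [
    "RankProfile",
    "EnrichmentConfig",
    "EnrichmentMatrix",
    "rank_transform",
    "enrichment_score",
    "score_all",
    "annotate",
]


@dataclass
class RankProfile:
    """Per-spot gene ranks and the descending-rank gene ordering."""

    ranks: np.ndarray  # rank per gene, input gene order; higher = more expressed
    order: np.ndarray  # gene indices sorted by descending rank

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        if self.ranks.size != self.order.size:
            raise ValueError("ranks and order must have equal length")


@dataclass
class EnrichmentConfig:
    alpha: float = 0.25
    normalize: str = "none"  # none | minmax (per set, across spots)
    tie_method: str = "average"  # average | ordinal

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError("alpha must be finite and >= 0")
        if self.normalize not in ("none", "minmax"):
            raise ValueError(f"unknown normalization {self.normalize!r}")
        if self.tie_method not in ("average", "ordinal"):
            raise ValueError(f"unknown tie method {self.tie_method!r}")


@dataclass
class EnrichmentMatrix:
    """Gene-set x spot matrix of enrichment scores."""

    values: np.ndarray
    set_names: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.set_names), len(self.spot_ids)):
            raise ValueError("enrichment matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("enrichment scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.set_names, columns=self.spot_ids
        )


def rank_transform(expr: np.ndarray, tie_method: str = "average") -> RankProfile:
    """Rank a spot's expression vector; ties by mean rank (or first-come order).

    The descending ordering breaks remaining ties by input gene index, so the
    walk down the list is deterministic.
    """
    expr = np.asarray(expr, dtype=float)
    if not np.all(np.isfinite(expr)):
        raise ValueError("expression must be finite")
    method = "average" if tie_method == "average" else "ordinal"
    ranks = rankdata(expr, method=method).astype(float)
    order = np.argsort(-ranks, kind="stable")
    return RankProfile(ranks, order)


def enrichment_score(
    profile: RankProfile,
    in_set: np.ndarray,
    config: EnrichmentConfig | None = None,
) -> float:
    """Mean difference between the weighted in-set CDF and the background CDF.

    ``in_set`` is a boolean mask over genes (input order).  Requires at least
    one in-set gene and at least one background gene.
    """
    config = config or EnrichmentConfig()
    in_set = np.asarray(in_set, dtype=bool)
    n = profile.ranks.size
    n_set = int(in_set.sum())
    if n_set == 0:
        raise ValueError("gene set does not intersect the measured genes")
    if n_set == n:
        raise ValueError("gene set covers all genes: empty background")

    mask = in_set[profile.order]
    w = profile.ranks[profile.order] ** config.alpha
    pos_num = np.cumsum(np.where(mask, w, 0.0))
    pos = pos_num / pos_num[-1]
    neg = np.cumsum(~mask) / (n - n_set)
    return float(np.mean(pos - neg))


def score_all(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    config: EnrichmentConfig | None = None,
    normalize_expr: bool = True,
    case_insensitive: bool = False,
) -> EnrichmentMatrix:
    """One enrichment score per (gene set, spot).

    Ranks are computed on library-size-normalized log1p expression by default;
    both transforms are monotone within a spot, so this only matters through
    tie structure.  Set genes absent from the matrix are ignored (a set losing
    all genes raises).  ``minmax`` normalization rescales each set's scores to
    [0, 1] across spots, which preserves the per-set ranking of spots.
    """
    config = config or EnrichmentConfig()
    work = normalize_expression(matrix) if normalize_expr else matrix
    gene_idx = work.gene_index()
    n_genes = work.n_genes

    masks = {}
    for name, genes in sets:
        present = match_genes(
            genes, work.gene_ids, case_insensitive, set_name=name
        )
        m = np.zeros(n_genes, dtype=bool)
        m[[gene_idx[g] for g in present]] = True
        masks[name] = m

    names = list(masks)
    values = np.empty((len(names), work.n_spots))
    for j in range(work.n_spots):
        profile = rank_transform(work.values[:, j], config.tie_method)
        for i, name in enumerate(names):
            values[i, j] = enrichment_score(profile, masks[name], config)

    if config.normalize == "minmax":
        lo = values.min(axis=1, keepdims=True)
        span = values.max(axis=1, keepdims=True) - lo
        span[span == 0] = 1.0
        values = (values - lo) / span

    return EnrichmentMatrix(values, names, list(work.spot_ids))


def annotate(es: EnrichmentMatrix) -> AnnotationResult:
    """Label each spot with the top-scoring set; margin = top minus runner-up.

    Exact score ties are broken by set-name order and logged.
    """
    if len(es.set_names) < 1:
        raise ValueError("need at least one gene set")
    name_order = np.argsort(np.asarray(es.set_names, dtype=object))
    vals = es.values[name_order]
    names = [es.set_names[i] for i in name_order]

    labels = []
    margins = np.zeros(len(es.spot_ids))
    for j in range(vals.shape[1]):
        col = vals[:, j]
        best = int(np.argmax(col))
        if np.count_nonzero(col == col[best]) > 1:
            logger.warning(
                "spot %s: tied top score, label %r chosen by name order",
                es.spot_ids[j], names[best],
            )
        labels.append(names[best])
        if col.size > 1:
            margins[j] = col[best] - np.partition(col, -2)[-2]

    scores = es.to_frame().T  # spots x sets
    return AnnotationResult(list(es.spot_ids), labels, scores, margins)
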