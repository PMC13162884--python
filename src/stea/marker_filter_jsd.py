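"""Spatial marker filtering by Jensen-Shannon divergence with permutation nulls.

A candidate gene is an efficient spatial marker when the 2D histogram of its
expression over the tissue closely matches that of the cell type's classical
markers.  For each candidate we compute

    JSD(Pg || Pm) = 1/2 KL(Pg || M) + 1/2 KL(Pm || M),   M = (Pg + Pm) / 2,

in nats (so JSD <= ln 2), against the reference distribution built from the
classical markers, and compare the observed value to a null distribution
obtained by permuting the candidate's expression across spots.  The empirical
p-value counts null JSDs at or below the observed one — small p means the
candidate tracks the reference pattern more tightly than chance.  P-values are
Benjamini-Hochberg adjusted across genes and candidates are kept at an FDR
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from statsmodels.stats.multitest import multipletests

from .data_io import (
    ExpressionMatrix,
    GeneSetCollection,
    SpotCoordinates,
    match_genes,
)
from .marker_expansion import build_reference_pattern, normalize_expression

logger = logging.getLogger("stea")

__all__ = [
    "SpatialDistribution",
    "PermutationConfig",
    "grid_cell_index",
    "build_spatial_histogram",
    "jensen_shannon_divergence",
    "permute_expression",
    "permutation_pvalue",
    "bh_adjust",
    "filter_markers",
]

DEFAULT_NBINS = 20
DEFAULT_PSEUDOCOUNT = 1e-10
DEFAULT_BLOCK_N_BINS = 10


@dataclass
class SpatialDistribution:
    """Normalized nbins x nbins probability grid for one gene."""

    grid: np.ndarray
    nbins: int
    x_edges: np.ndarray
    y_edges: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (self.nbins, self.nbins):
            raise ValueError("grid shape does not match nbins")
        if np.any(self.grid <= 0):
            raise ValueError("grid cells must be strictly positive")
        if abs(self.grid.sum() - 1.0) > 1e-9:
            raise ValueError("grid must sum to 1")


@dataclass
class PermutationConfig:
    n_perm: int = 1000
    mode: str = "random"
    block_n_bins: int = DEFAULT_BLOCK_N_BINS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.mode not in ("random", "spatial_blocks"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.block_n_bins < 1:
            raise ValueError("block_n_bins must be >= 1")


def _bin_edges(v: np.ndarray, nbins: int) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        hi = lo + 1.0  # constant axis: everything lands in bin 0
    return np.linspace(lo, hi, nbins + 1)


def _axis_index(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # equal-width binning; rightmost edge inclusive
    nbins = edges.size - 1
    width = edges[-1] - edges[0]
    idx = np.floor((v - edges[0]) / width * nbins).astype(int)
    return np.clip(idx, 0, nbins - 1)


def grid_cell_index(
    coords: SpotCoordinates, nbins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat grid-cell index per spot plus the bin edges.

    Precomputing this makes re-binning a permuted expression vector a single
    ``np.bincount`` call, which is what keeps permutation nulls cheap.
    """
    if np.all(coords.x == coords.x[0]) and np.all(coords.y == coords.y[0]):
        raise ValueError("all spot coordinates identical: degenerate grid")
    x_edges = _bin_edges(coords.x, nbins)
    y_edges = _bin_edges(coords.y, nbins)
    ix = _axis_index(coords.x, x_edges)
    iy = _axis_index(coords.y, y_edges)
    return ix * nbins + iy, x_edges, y_edges


def _histogram_from_index(
    expr: np.ndarray,
    cell_idx: np.ndarray,
    nbins: int,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    pseudocount: float,
) -> SpatialDistribution:
    grid = np.bincount(cell_idx, weights=expr, minlength=nbins * nbins)
    grid = grid.reshape(nbins, nbins) + pseudocount
    return SpatialDistribution(grid / grid.sum(), nbins, x_edges, y_edges)


def build_spatial_histogram(
    expr: np.ndarray,
    coords: SpotCoordinates,
    nbins: int = DEFAULT_NBINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SpatialDistribution:
    """Accumulate expression mass on an nbins x nbins grid and normalize.

    A pseudocount is added to every cell before normalization so that the
    divergence below is always finite; with all-zero expression the result is
    the uniform distribution.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.size != coords.n_spots:
        raise ValueError("expression length does not match coordinates")
    if np.any(expr < 0):
        raise ValueError("expression must be non-negative")
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    cell_idx, x_edges, y_edges = grid_cell_index(coords, nbins)
    return _histogram_from_index(
        expr, cell_idx, nbins, x_edges, y_edges, pseudocount
    )


def jensen_shannon_divergence(
    P: SpatialDistribution | np.ndarray, Q: SpatialDistribution | np.ndarray
) -> float:
    """JSD between two probability grids in nats; symmetric, in [0, ln 2]."""
    p = P.grid if isinstance(P, SpatialDistribution) else np.asarray(P, float)
    q = Q.grid if isinstance(Q, SpatialDistribution) else np.asarray(Q, float)
    if p.shape != q.shape:
        raise ValueError(f"grid shape mismatch: {p.shape} vs {q.shape}")
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def permute_expression(
    expr: np.ndarray,
    coords: SpotCoordinates,
    mode: str = "random",
    block_n_bins: int = DEFAULT_BLOCK_N_BINS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Return a permutation of ``expr`` under the chosen null model.

    ``random`` permutes values uniformly across all spots.  ``spatial_blocks``
    partitions the tissue into a block grid and moves each occupied block's
    values, as a contiguous chunk, to the position of another block chosen
    uniformly at random: within-block value order is preserved while the
    global pattern is broken.  Both modes conserve the value multiset exactly;
    when block occupancies differ, chunks spill across block boundaries rather
    than being truncated.
    """
    rng = np.random.default_rng() if rng is None else rng
    expr = np.asarray(expr, dtype=float)
    if mode == "random":
        return rng.permutation(expr)
    if mode != "spatial_blocks":
        raise ValueError(f"unknown permutation mode {mode!r}")

    block_idx, _, _ = grid_cell_index(coords, max(block_n_bins, 2)) \
        if block_n_bins >= 2 else (np.zeros(expr.size, dtype=int), None, None)
    blocks = np.unique(block_idx)
    spots_by_block = [np.flatnonzero(block_idx == b) for b in blocks]
    perm = rng.permutation(len(blocks))
    values = np.concatenate([expr[spots_by_block[j]] for j in perm])
    out = np.empty_like(expr)
    out[np.concatenate(spots_by_block)] = values
    return out


def permutation_pvalue(observed: float, nulls, n_perm: int) -> float:
    """Empirical p = (#{null <= observed} + 1) / (n_perm + 1)."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if nulls.size != n_perm:
        raise ValueError(f"expected {n_perm} null values, got {nulls.size}")
    return float((np.count_nonzero(nulls <= observed) + 1) / (n_perm + 1))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, gene order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_markers(
    matrix: ExpressionMatrix,
    coords: SpotCoordinates,
    candidates: GeneSetCollection,
    classical: GeneSetCollection,
    config: PermutationConfig | None = None,
    alpha_fdr: float = 0.05,
    nbins: int = DEFAULT_NBINS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    per_marker: str = "mean",
    normalize: bool = True,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Keep candidate markers whose spatial pattern matches the classical one.

    For every candidate gene not already classical, the observed JSD against
    the cell type's reference distribution is compared with ``config.n_perm``
    permutation nulls; genes with BH-adjusted p <= ``alpha_fdr`` are kept.
    Classical markers are always kept.  ``per_marker="min"`` scores each
    candidate against each classical marker separately and takes the minimum
    JSD instead of using the mean-marker reference.
    """
    config = config or PermutationConfig()
    if matrix.spot_ids != coords.spot_ids:
        raise ValueError("matrix and coordinates disagree on spot ids")
    work = normalize_expression(matrix, log1p=False) if normalize else matrix
    gene_idx = work.gene_index()
    cell_idx, x_edges, y_edges = grid_cell_index(coords, nbins)
    rng = np.random.default_rng(config.seed)

    def hist(v: np.ndarray) -> SpatialDistribution:
        return _histogram_from_index(
            v, cell_idx, nbins, x_edges, y_edges, pseudocount
        )

    rows: list[dict] = []
    for cell_type, cand_genes in candidates:
        if cell_type not in classical.sets:
            raise ValueError(f"no classical markers for cell type {cell_type!r}")
        classical_genes = match_genes(
            classical.sets[cell_type], work.gene_ids, set_name=cell_type
        )
        if per_marker == "min":
            refs = [hist(work.values[gene_idx[g]]) for g in classical_genes]
        else:
            pattern = build_reference_pattern(
                work, classical_genes, cell_type, agg="mean"
            )
            refs = [hist(pattern.values)]

        def observed_jsd(v: np.ndarray) -> float:
            h = hist(v)
            return min(jensen_shannon_divergence(h, r) for r in refs)

        classical_set = set(classical.sets[cell_type]) | set(classical_genes)
        for gene in cand_genes:
            if gene in classical_set or gene not in gene_idx:
                continue
            expr = work.values[gene_idx[gene]]
            obs = observed_jsd(expr)
            nulls = np.empty(config.n_perm)
            for i in range(config.n_perm):
                perm = permute_expression(
                    expr, coords, config.mode, config.block_n_bins, rng
                )
                nulls[i] = observed_jsd(perm)
            rows.append(
                {
                    "gene": gene,
                    "cell_type": cell_type,
                    "jsd": obs,
                    "p_value": permutation_pvalue(obs, nulls, config.n_perm),
                }
            )

    results = pd.DataFrame(
        rows, columns=["gene", "cell_type", "jsd", "p_value"]
    )
    if len(results):
        results["adjusted_p"] = bh_adjust(results["p_value"].to_numpy())
        results["kept"] = results["adjusted_p"] <= alpha_fdr
    else:
        results["adjusted_p"] = pd.Series(dtype=float)
        results["kept"] = pd.Series(dtype=bool)

    kept_lookup = {
        (r.cell_type, r.gene): bool(r.kept) for r in results.itertuples()
    }
    filtered: dict[str, list[str]] = {}
    for cell_type, cand_genes in candidates:
        classical_genes = list(classical.sets[cell_type])
        keep = [
            g
            for g in cand_genes
            if g not in classical_genes
            and kept_lookup.get((cell_type, g), False)
        ]
        filtered[cell_type] = classical_genes + keep
    for cell_type in classical.sets:
        filtered.setdefault(cell_type, list(classical.sets[cell_type]))
    return GeneSetCollection(filtered), results
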