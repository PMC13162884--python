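"""Marker-set expansion by cosine similarity to a reference spatial pattern.

Each cell type's classical markers are summarized into a reference pattern
lambda_k over spots (arithmetic mean of their normalized expression vectors by
default).  Every other gene g is scored by

    cos(g, lambda) = sum_j x_j * lambda_j / (||x|| * ||lambda||),

and the top-ranked candidates above a similarity cutoff are appended to the
set.  Cosine similarity is scale-invariant, so a gene that tracks the marker
pattern is recovered regardless of its absolute expression level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSetCollection, match_genes

logger = logging.getLogger("stea")

__all__ = [
    "ReferencePattern",
    "normalize_expression",
    "build_reference_pattern",
    "cosine_similarity",
    "expand_markers",
]


@dataclass
class ReferencePattern:
    """Aggregate spot-wise profile summarizing one cell type's markers."""

    values: np.ndarray
    source_genes: list[str]
    cell_type: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.all(self.values == 0):
            raise ValueError(
                f"reference pattern for {self.cell_type!r} is all-zero"
            )


def normalize_expression(
    matrix: ExpressionMatrix,
    target_sum: float | None = None,
    log1p: bool = True,
) -> ExpressionMatrix:
    """Library-size normalize each spot, optionally followed by log1p.

    Spot totals are scaled to ``target_sum`` (median spot depth when None).
    Spots with zero total are left as zero.  Cosine similarity and the spatial
    histograms are computed on the linear scale (``log1p=False``): the log
    compresses fold changes toward the shared baseline and washes out the
    very contrast those steps rely on.
    """
    totals = matrix.values.sum(axis=0)
    if target_sum is None:
        nz = totals[totals > 0]
        target_sum = float(np.median(nz)) if nz.size else 1.0
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals, dtype=float),
        where=totals > 0,
    )
    values = matrix.values * scale
    if log1p:
        values = np.log1p(values)
    return ExpressionMatrix(values, list(matrix.gene_ids), list(matrix.spot_ids))


def build_reference_pattern(
    matrix: ExpressionMatrix,
    markers: list[str],
    cell_type: str,
    agg: str = "mean",
    case_insensitive: bool = False,
) -> ReferencePattern:
    """Aggregate the expression vectors of the present markers into one pattern."""
    present = match_genes(
        markers, matrix.gene_ids, case_insensitive, set_name=cell_type
    )
    idx = matrix.gene_index()
    sub = matrix.values[[idx[g] for g in present]]
    if agg == "mean":
        values = sub.mean(axis=0)
    elif agg == "median":
        values = np.median(sub, axis=0)
    else:
        raise ValueError(f"unknown aggregation {agg!r}")
    return ReferencePattern(values, present, cell_type)


def cosine_similarity(g: np.ndarray, lam: np.ndarray) -> float:
    """Cosine of the angle between two spot-length vectors; 0 for a zero vector."""
    g = np.asarray(g, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if g.shape != lam.shape:
        raise ValueError(f"length mismatch: {g.shape} vs {lam.shape}")
    ng, nl = np.linalg.norm(g), np.linalg.norm(lam)
    if ng == 0 or nl == 0:
        logger.warning("cosine similarity of an all-zero vector defined as 0")
        return 0.0
    return float(np.dot(g, lam) / (ng * nl))


def _cosine_all_genes(values: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Cosine of every matrix row against one pattern (zero rows score 0)."""
    norms = np.linalg.norm(values, axis=1)
    nl = np.linalg.norm(lam)
    dots = values @ lam
    out = np.zeros(values.shape[0])
    ok = (norms > 0) & (nl > 0)
    out[ok] = dots[ok] / (norms[ok] * nl)
    return out


def expand_markers(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    top_n: int = 20,
    min_similarity: float = 0.5,
    normalize: bool = True,
    agg: str = "mean",
    case_insensitive: bool = False,
) -> tuple[GeneSetCollection, dict[str, pd.DataFrame]]:
    """Append up to ``top_n`` co-localized candidate genes per cell type.

    Returns the expanded collection (original markers first, in order) and a
    per-type ranking of all non-marker genes by descending cosine similarity.
    A candidate exceeding the cutoff for several types is kept in all of them;
    discrimination between types is the job of the downstream spatial filter.
    """
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    if not 0.0 <= min_similarity <= 1.0:
        raise ValueError("min_similarity must lie in [0, 1]")

    work = normalize_expression(matrix, log1p=False) if normalize else matrix
    expanded: dict[str, list[str]] = {}
    rankings: dict[str, pd.DataFrame] = {}
    assigned: dict[str, str] = {}

    for cell_type, markers in collection:
        pattern = build_reference_pattern(
            work, markers, cell_type, agg=agg, case_insensitive=case_insensitive
        )
        marker_set = set(pattern.source_genes) | set(markers)
        sims = _cosine_all_genes(work.values, pattern.values)
        candidates = [
            i for i, g in enumerate(work.gene_ids) if g not in marker_set
        ]
        order = sorted(candidates, key=lambda i: -sims[i])
        ranking = pd.DataFrame(
            {
                "gene": [work.gene_ids[i] for i in order],
                "similarity": [sims[i] for i in order],
            }
        )
        rankings[cell_type] = ranking

        added: list[str] = []
        for i in order[: top_n if top_n else 0]:
            if sims[i] < min_similarity:
                break
            gene = work.gene_ids[i]
            added.append(gene)
            if gene in assigned and assigned[gene] != cell_type:
                logger.info(
                    "gene %r added to both %r and %r",
                    gene, assigned[gene], cell_type,
                )
            assigned[gene] = cell_type
        expanded[cell_type] = list(markers) + added

    return GeneSetCollection(expanded), rankings
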