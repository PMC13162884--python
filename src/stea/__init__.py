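"""STEA: reference-independent major cell-type annotation for spatial transcriptomics.

Three stages: (1) optionally expand classical marker sets with genes whose
spatial expression pattern has high cosine similarity to the markers'; (2)
optionally filter candidates by the Jensen-Shannon divergence between their 2D
spatial histograms and the classical markers', with permutation-test
significance and BH correction; (3) score every (gene set, spot) pair with a
rank-CDF enrichment statistic and label each spot with its top-scoring type.
"""

from __future__ import annotations

import logging

from .data_io import (
    AnnotationResult,
    ExpressionMatrix,
    GeneSetCollection,
    SpotCoordinates,
    match_genes,
    read_annotation,
    read_config,
    read_coordinates,
    read_expression,
    read_gene_sets,
    write_annotation,
    write_coordinates,
    write_expression_mtx,
    write_gene_sets,
)
from .enrichment_annotation import (
    EnrichmentConfig,
    EnrichmentMatrix,
    RankProfile,
    annotate,
    enrichment_score,
    rank_transform,
    score_all,
)
from .evaluation_consensus import (
    ConsensusMatrix,
    accuracy,
    consensus_ground_truth,
    consensus_matrix,
    extract_consensus_blocks,
    index_of_dispersion,
    leiden_clusterer,
    per_type_accuracy,
)
from .marker_expansion import (
    ReferencePattern,
    build_reference_pattern,
    cosine_similarity,
    expand_markers,
    normalize_expression,
)
from .marker_filter_jsd import (
    PermutationConfig,
    SpatialDistribution,
    bh_adjust,
    build_spatial_histogram,
    filter_markers,
    jensen_shannon_divergence,
    permutation_pvalue,
    permute_expression,
)
from .simulator import (
    PseudoSpotDataset,
    ReferenceParams,
    SyntheticReference,
    generate_dataset,
    generate_pseudospot,
    generate_reference,
    write_dataset,
)

__version__ = "0.1.0"

logging.getLogger("stea").addHandler(logging.NullHandler())


def run_pipeline(
    matrix: ExpressionMatrix,
    coords: SpotCoordinates,
    markers: GeneSetCollection,
    expand: bool = True,
    filter_candidates: bool = True,
    top_n: int = 20,
    min_similarity: float = 0.5,
    permutation: PermutationConfig | None = None,
    alpha_fdr: float = 0.05,
    nbins: int = 20,
    enrichment: EnrichmentConfig | None = None,
) -> AnnotationResult:
    """End-to-end annotation: expand -> filter -> score -> label.

    Both refinement stages are optional; with both disabled this reduces to
    enrichment scoring of the classical marker sets.

    Scores are min-max normalized per set across spots by default: marker
    signatures differ widely in expression strength, and without per-set
    calibration the argmax is biased toward the strongest set.
    """
    if enrichment is None:
        enrichment = EnrichmentConfig(normalize="minmax")
    sets = markers
    if expand:
        sets, _ = expand_markers(
            matrix, markers, top_n=top_n, min_similarity=min_similarity
        )
    if filter_candidates and sets is not markers:
        sets, _ = filter_markers(
            matrix, coords, sets, markers,
            config=permutation, alpha_fdr=alpha_fdr, nbins=nbins,
        )
    es = score_all(matrix, sets, config=enrichment)
    return annotate(es)


__all__ = [name for name in dir() if not name.startswith("_")]
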