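# Methods

## Problem and approach

Sequencing-based spatial transcriptomics platforms (Visium and relatives)
capture transcripts in spots of ~55 µm that each cover several cells, so a
spot's expression profile is a mixture over cell types. This package annotates
each spot with its *major* cell type — the type contributing the plurality of
cells — without a matched single-cell reference. It needs only a list of
classical marker genes per cell type and proceeds in three stages:

1. **Marker expansion (optional).** Each cell type's markers are summarized
   into a reference pattern λ over spots; every other gene g is scored by
   cosine similarity cos(g, λ) = Σ xⱼλⱼ / (‖x‖‖λ‖) and the top-ranked
   candidates above a cutoff join the set.
2. **Spatial filtering (optional).** Each candidate's expression is binned
   onto an `nbins × nbins` grid over the tissue and compared with the
   classical markers' grid by the Jensen–Shannon divergence
   JSD(P‖Q) = ½KL(P‖M) + ½KL(Q‖M), M = ½(P+Q), in nats. Significance comes
   from permutation nulls; candidates are kept at a Benjamini–Hochberg FDR
   threshold.
3. **Enrichment scoring and annotation.** Per spot, genes are ranked, ordered
   descending, and weighted wⱼ = R_π(j)^α. The enrichment score of set S is
   the mean pointwise difference between the weighted in-set CDF and the
   uniform background CDF along the ordered list — the average area between
   the two curves, not a running-sum maximum as in classical GSEA. The spot's
   label is the argmax over sets.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `top_n` | 20 | candidates appended per cell type at expansion |
| `min_similarity` | 0.5 | cosine cutoff for candidates (on [0, 1] for non-negative data) |
| `nbins` | 20 | side of the 2D histogram grid |
| pseudocount | 1e-10 | added to every grid cell before normalization (keeps KL finite) |
| `n_perm` | 1000 | permutation iterations (tests and pipeline runs use 200) |
| `block_n_bins` | 10 | side of the coarse block grid for the spatial-blocks null |
| `alpha_fdr` | 0.05 | BH threshold for keeping a candidate |
| `alpha` | 0.25 | rank-weight exponent; larger values emphasize top-ranked genes |
| `normalize` | minmax (pipeline) | per-set min–max calibration of scores across spots |

## Numerical and design choices

**Expression scale.** Cosine similarity and the spatial histograms are
computed on library-size-normalized *linear* expression. The log1p transform,
standard for PCA and clustering, compresses fold changes toward the shared
non-negative baseline: on synthetic data with fold-change-5 markers it
collapses the cosine gap between truly co-expressed genes and flat
housekeeping-like genes (both reach ~0.99) and expansion stops recovering
planted genes, while the linear scale separates them cleanly (~0.9 vs ~0.78).
Ranking for the enrichment score is invariant to both transforms (they are
monotone within a spot), so scores are unaffected by this choice.

**Score calibration across sets.** Marker signatures differ widely in
expression strength, and the raw enrichment score inherits that: with
heterogeneous sets the argmax drifts toward the strongest signature (on the
benchmark below, raw-score accuracy is 0.72 with errors concentrated on the
weakest-marker type, versus 0.97 calibrated). The annotation pipeline
therefore min–max normalizes each set's scores across spots before the
argmax; the rescaling is monotone per set, so per-set spot rankings are
unchanged. The `score_all` primitive leaves scores raw unless asked.

**Histogram convention.** Equal-width bins span [min, max] of each coordinate
with the rightmost edge inclusive; a constant axis degenerates to a single
occupied bin column, and fully identical coordinates are an error. The
spot→cell assignment is precomputed once so each permutation null re-bins via
a single `bincount`.

**Permutation nulls.** `random` mode permutes values uniformly across spots.
`spatial_blocks` mode partitions the tissue into a coarse block grid and
moves each occupied block's values as a contiguous chunk to the position of a
uniformly chosen block, preserving within-block order. Both modes conserve
the value multiset exactly; with unequal block occupancies chunks spill
across block boundaries rather than being truncated. The empirical p-value is
(#{null ≤ observed} + 1)/(n_perm + 1): *low* p means the candidate matches the
reference pattern more tightly than chance, so "significant" genes are kept,
not rejected. Nulls reuse the observed statistic's nbins and pseudocount.

**Enrichment score conventions.** Ties get average ranks (ordinal available);
the descending order breaks remaining ties by input gene index, so scoring is
deterministic and invariant to gene order in the input file. Zero-count genes
keep their (tied lowest) ranks so N is constant across spots. The score needs
at least one in-set and one background gene; both degenerate cases raise.
At α = 0 the weighted CDF reduces to the plain in-set empirical CDF and a
uniformly random set has mean score ≈ 0; for α > 0 the weighting adds a small
positive offset (~0.05 at N = 40) common to all sets, which cancels at the
argmax. Scores stay within (−1, 1).

**Consensus surrogate truth.** The resolution sweep (0.1–1.0, step 0.1) uses
a pluggable clusterer; the built-in default is Leiden on a symmetrized
15-nearest-neighbour graph of the top 30 PCs of log1p expression, with the
RB-configuration resolution parameter. Blocks are extracted by average-linkage
hierarchical clustering of 1 − consensus cut at a user-chosen block count
(block count selection is left to the user). Accuracy matches labels by name;
no Hungarian matching is performed.

## What the simulator emulates — and what it does not

The synthetic single-cell reference draws negative-binomial counts
(shared dispersion 0.5, i.e. variance μ + 0.5μ²) with log-normal per-gene
base means (σ = 1) scaled to an expected depth of 2,000 counts per cell over
2,000 genes — roughly a filtered, moderately deep droplet experiment. Each of
six types (named for a liver-tumor microenvironment: malignant, CAF, TEC, B,
T, TAM) gets 10 planted markers whose mean is multiplied by fold_change
(default 5) in its own type only.

Pseudo-spots sum 3, 5 or 10 cells (drawn with replacement), with a uniformly
random major type and a major fraction uniform on [0.6, 1.0]; the major-cell
count is round-half-up of fraction × pool, clamped to keep ≥ 60%. Coordinates
are a deterministic square grid: pseudo-spots carry no spatial
autocorrelation, which keeps spatial operations exercisable but means the JSD
filter's discrimination here comes entirely from spot-level co-expression,
not from tissue architecture. Real tissues add spatially structured noise,
batch effects, segment-specific depth and markers whose specificity is far
from uniform — passing on this benchmark shows the machinery is correct and
well-calibrated, not that any marker list will annotate any tissue.

Problem sizes used by the test suite and the reproduction script — 10,000
spots for the design-scale check, 1,000-spot pipelines for accuracy, 5
repeats for the dispersion summary, n_perm = 200 — were chosen as the package's
standard benchmark configuration; the dataset design itself (10,000 spots,
6 types, pools {3, 5, 10}, 60–100% majority) is fixed.

## Known limitations

- Annotation is categorical: scores indicate the extent of enrichment, not
  calibrated cell-type proportions.
- Types absent from the marker collection cannot be predicted; sets that lose
  all their genes against the matrix raise rather than silently scoring.
- The JSD filter assumes candidates were proposed for the *right* cell type;
  it measures pattern match against that type's reference only.
- With very sparse spots (few hundred counts), rank ties among zeros dominate
  and scores flatten; deeper filtering of the gene universe is the user's
  responsibility.
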