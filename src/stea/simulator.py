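"""Pseudo-spot simulator with ground-truth major cell types.

Pseudo-spots emulate sequencing-based spatial capture regions: each spot sums
the count vectors of a small pool of single cells (3, 5 or 10, mimicking cell
size/density heterogeneity), of which one designated major type contributes
60-100% of the pool.  The single-cell source is a synthetic negative-binomial
reference with planted type-specific marker genes, so the whole benchmark is
generated in memory with no external download.  Defaults mirror a liver-tumor
microenvironment with six major types: malignant cells, cancer-associated
fibroblasts (CAF), tumor-associated endothelial cells (TEC), B cells, T cells
and tumor-associated macrophages (TAM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSetCollection, SpotCoordinates

__all__ = [
    "ReferenceParams",
    "SyntheticReference",
    "PseudoSpotDataset",
    "generate_reference",
    "generate_pseudospot",
    "generate_dataset",
    "write_dataset",
]

DEFAULT_TYPE_NAMES = ("malignant", "CAF", "TEC", "B", "T", "TAM")
POOL_SIZES = (3, 5, 10)
MIN_MAJOR_FRACTION = 0.6


@dataclass
class ReferenceParams:
    """Knobs of the synthetic single-cell reference.

    Counts follow a negative binomial with log-normal per-gene base means
    scaled to an expected per-cell depth; each planted marker's mean is
    multiplied by ``fold_change`` in its own type only.
    """

    n_types: int = 6
    type_names: tuple[str, ...] = DEFAULT_TYPE_NAMES
    n_genes: int = 2000
    cells_per_type: int = 200
    markers_per_type: int = 10
    fold_change: float = 5.0
    dispersion: float = 0.5
    depth: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.markers_per_type < 1:
            raise ValueError("need at least 1 planted marker per type")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.type_names) != self.n_types:
            self.type_names = tuple(
                f"type{i + 1}" for i in range(self.n_types)
            )
        if self.n_genes < self.n_types * self.markers_per_type:
            raise ValueError("not enough genes to plant all markers")


@dataclass
class SyntheticReference:
    cell_profiles: np.ndarray  # cells x genes, integer counts
    cell_types: list[str]
    gene_ids: list[str]
    marker_map: GeneSetCollection
    params: ReferenceParams

    def __post_init__(self) -> None:
        if np.any(self.cell_profiles < 0):
            raise ValueError("counts must be non-negative")
        for t in self.params.type_names:
            if t not in self.cell_types:
                raise ValueError(f"type {t!r} has no cells")

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        cache = getattr(self, "_type_cache", None)
        if cache is None:
            arr = np.asarray(self.cell_types)
            cache = {t: np.flatnonzero(arr == t) for t in set(self.cell_types)}
            object.__setattr__(self, "_type_cache", cache)
        return cache[cell_type]


@dataclass
class PseudoSpotDataset:
    matrix: ExpressionMatrix
    coords: SpotCoordinates
    truth: list[str]
    composition: pd.DataFrame  # spots x types, constituent-cell counts
    pool_size: np.ndarray
    major_fraction: np.ndarray
    marker_map: GeneSetCollection = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pool_size = np.asarray(self.pool_size, dtype=int)
        self.major_fraction = np.asarray(self.major_fraction, dtype=float)
        totals = self.composition.to_numpy().sum(axis=1)
        if not np.array_equal(totals, self.pool_size):
            raise ValueError("composition does not sum to pool_size")
        maxes = self.composition.to_numpy().max(axis=1)
        if not np.allclose(self.major_fraction, maxes / self.pool_size):
            raise ValueError("major_fraction inconsistent with composition")
        if np.any(self.major_fraction < MIN_MAJOR_FRACTION - 1e-12):
            raise ValueError("a spot violates the 60% major-fraction floor")
        argmax = self.composition.idxmax(axis=1).tolist()
        if argmax != list(self.truth):
            raise ValueError("truth labels disagree with composition argmax")

    @property
    def n_spots(self) -> int:
        return self.matrix.n_spots


def generate_reference(
    params: ReferenceParams | None = None, seed: int = 0
) -> SyntheticReference:
    """Draw the synthetic single-cell reference with planted markers."""
    params = params or ReferenceParams()
    rng = np.random.default_rng(seed)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=params.n_genes)
    base = base / base.sum() * params.depth  # expected counts per cell

    gene_ids = [f"G{i + 1:05d}" for i in range(params.n_genes)]
    marker_sets: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    for k, name in enumerate(params.type_names):
        lo = k * params.markers_per_type
        idx = np.arange(lo, lo + params.markers_per_type)
        marker_idx[name] = idx
        marker_sets[name] = [gene_ids[i] for i in idx]

    n_cells = params.n_types * params.cells_per_type
    profiles = np.empty((n_cells, params.n_genes), dtype=np.int64)
    cell_types: list[str] = []
    row = 0
    for name in params.type_names:
        mu = base.copy()
        mu[marker_idx[name]] *= params.fold_change
        shape = (params.cells_per_type, params.n_genes)
        if params.dispersion == 0:
            counts = rng.poisson(mu, size=shape)
        else:
            r = 1.0 / params.dispersion
            counts = rng.negative_binomial(r, r / (r + mu), size=shape)
        profiles[row : row + params.cells_per_type] = counts
        cell_types.extend([name] * params.cells_per_type)
        row += params.cells_per_type

    return SyntheticReference(
        profiles, cell_types, gene_ids, GeneSetCollection(marker_sets), params
    )


def _n_major(pool_size: int, major_fraction_target: float) -> int:
    """Round-half-up the target count, clamped to keep the >= 60% floor."""
    n = math.floor(major_fraction_target * pool_size + 0.5)
    n = max(n, math.ceil(MIN_MAJOR_FRACTION * pool_size))
    return min(n, pool_size)


def generate_pseudospot(
    ref: SyntheticReference,
    major_type: str,
    pool_size: int,
    major_fraction_target: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, int], np.ndarray]:
    """One pseudo-spot: summed counts, per-type composition, sampled cell rows."""
    if major_type not in ref.params.type_names:
        raise ValueError(f"unknown cell type {major_type!r}")
    if not MIN_MAJOR_FRACTION <= major_fraction_target <= 1.0:
        raise ValueError("major fraction target must lie in [0.6, 1.0]")
    n_major = _n_major(pool_size, major_fraction_target)
    if n_major / pool_size < MIN_MAJOR_FRACTION:
        raise ValueError(
            f"pool_size {pool_size} cannot honour a 60% major fraction"
        )
    others = [t for t in ref.params.type_names if t != major_type]
    minor_types = rng.choice(others, size=pool_size - n_major, replace=True)

    cells = list(rng.choice(ref.cells_of_type(major_type), n_major, replace=True))
    composition = {t: 0 for t in ref.params.type_names}
    composition[major_type] = n_major
    for t in minor_types:
        cells.append(rng.choice(ref.cells_of_type(t)))
        composition[t] += 1
    cells = np.asarray(cells, dtype=int)
    vector = ref.cell_profiles[cells].sum(axis=0)
    return vector, composition, cells


def _square_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    side = math.ceil(math.sqrt(n))
    idx = np.arange(n)
    return (idx % side).astype(float), (idx // side).astype(float)


def generate_dataset(
    ref: SyntheticReference,
    n_spots: int = 10_000,
    repeats: int = 1,
    grid_layout: bool = True,
    seed: int = 0,
    pool_sizes: tuple[int, ...] = POOL_SIZES,
) -> list[PseudoSpotDataset]:
    """Stochastically repeated pseudo-spot datasets with recorded ground truth.

    Per spot: a uniformly random major type, a pool size drawn from
    ``pool_sizes`` and a major-fraction target uniform on [0.6, 1.0].
    Coordinates are a deterministic square grid (pseudo-spots carry no real
    spatial signal; the grid keeps spatial operations exercisable downstream).
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    rng = np.random.default_rng(seed)
    types = list(ref.params.type_names)
    datasets = []
    for rep in range(repeats):
        majors = rng.choice(types, size=n_spots, replace=True)
        pools = rng.choice(np.asarray(pool_sizes), size=n_spots, replace=True)
        fracs = rng.uniform(MIN_MAJOR_FRACTION, 1.0, size=n_spots)

        values = np.zeros((n_spots, len(ref.gene_ids)), dtype=np.int64)
        comp = np.zeros((n_spots, len(types)), dtype=int)
        type_col = {t: i for i, t in enumerate(types)}
        for j in range(n_spots):
            vec, composition, _ = generate_pseudospot(
                ref, majors[j], int(pools[j]), float(fracs[j]), rng
            )
            values[j] = vec
            for t, c in composition.items():
                comp[j, type_col[t]] = c

        spot_ids = [f"spot{j + 1:05d}" for j in range(n_spots)]
        if grid_layout:
            x, y = _square_grid(n_spots)
        else:
            x = rng.uniform(0, 1, n_spots)
            y = rng.uniform(0, 1, n_spots)
        matrix = ExpressionMatrix(values.T, list(ref.gene_ids), spot_ids)
        datasets.append(
            PseudoSpotDataset(
                matrix=matrix,
                coords=SpotCoordinates(spot_ids, x, y),
                truth=list(majors),
                composition=pd.DataFrame(comp, index=spot_ids, columns=types),
                pool_size=pools,
                major_fraction=comp.max(axis=1) / pools,
                marker_map=ref.marker_map,
            )
        )
    return datasets


def write_dataset(ds: PseudoSpotDataset, out_dir) -> None:
    """Write matrix (MTX dir), coords TSV, truth CSV and the planted-marker GMT."""
    from pathlib import Path

    from .data_io import write_coordinates, write_expression_mtx, write_gene_sets

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_mtx(ds.matrix, out / "matrix")
    write_coordinates(ds.coords, out / "coords.tsv")
    pd.DataFrame({"spot_id": ds.matrix.spot_ids, "truth": ds.truth}).to_csv(
        out / "truth.csv", index=False
    )
    if ds.marker_map is not None:
        write_gene_sets(ds.marker_map, out / "markers.gmt")
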