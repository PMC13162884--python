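"""Readers, writers and core containers for the annotation toolkit.

Expression is stored genes x spots (the 10x features-x-barcodes convention).
Supported on-disk dialects: MatrixMarket triplet directories (matrix.mtx +
features.tsv + barcodes.tsv, gzipped or plain), dense CSV/TSV with gene rows
and spot columns, GMT or two-column TSV gene sets, and TSV coordinates with
columns spot_id, x, y.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("stea")

__all__ = [
    "ExpressionMatrix",
    "SpotCoordinates",
    "GeneSetCollection",
    "AnnotationResult",
    "read_expression",
    "write_expression_mtx",
    "read_coordinates",
    "write_coordinates",
    "read_gene_sets",
    "write_gene_sets",
    "write_annotation",
    "read_annotation",
    "read_config",
    "match_genes",
]


def _check_unique(ids, what: str) -> None:
    seen: dict = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = True
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x spots expression values (counts or normalized)."""

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.spot_ids = [str(s) for s in self.spot_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.spot_ids)} spots"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.spot_ids, "spot ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression contains non-finite values")
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.gene_ids[g]!r}, "
                f"spot {self.spot_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def gene_vector(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index()[gene]]


@dataclass
class SpotCoordinates:
    """2D Cartesian coordinates, one pair per spot."""

    spot_ids: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.spot_ids = [str(s) for s in self.spot_ids]
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.spot_ids) == self.x.size == self.y.size):
            raise ValueError("spot_ids, x and y must have equal length")
        _check_unique(self.spot_ids, "spot ids")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)


@dataclass
class GeneSetCollection:
    """Named cell-type marker sets; order within a set is preserved."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            _check_unique(genes, f"genes in set {name!r}")

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSetCollection) and self.sets == other.sets

    def __iter__(self):
        return iter(self.sets.items())

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class AnnotationResult:
    """Winning cell-type label per spot with per-type scores and margin."""

    spot_ids: list[str]
    labels: list[str]
    scores: pd.DataFrame  # spots x cell types
    margin: np.ndarray

    def __post_init__(self) -> None:
        self.margin = np.asarray(self.margin, dtype=float)
        n = len(self.spot_ids)
        if not (len(self.labels) == n == self.scores.shape[0] == self.margin.size):
            raise ValueError("inconsistent annotation result lengths")
        valid = set(self.scores.columns)
        bad = [l for l in self.labels if l not in valid]
        if bad:
            raise ValueError(f"labels not among scored cell types: {bad[:5]}")
        if np.any(self.margin < 0):
            raise ValueError("margin must be non-negative")


# ---------------------------------------------------------------------------
# expression matrices


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_one(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FileNotFoundError(
        f"none of {stems} (or .gz) found in directory {directory}"
    )


def _read_id_column(path: Path) -> list[str]:
    # 10x features files carry (id, symbol, type); prefer the symbol column
    # because marker sets are keyed by symbol. Single-column files pass through.
    with _open_maybe_gz(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if rows and len(rows[0]) >= 2:
        return [r[1] for r in rows]
    return [r[0] for r in rows]


def read_expression(
    path, format: str = "auto", transpose: bool = False
) -> ExpressionMatrix:
    """Read an expression matrix from an MTX directory or a dense CSV/TSV.

    Files are assumed genes x spots; pass ``transpose=True`` for spots x genes
    sources. Gene/spot order in the file is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format == "auto":
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix.lower() == ".csv":
            format = "csv"
        else:
            format = "tsv"

    if format == "mtx_dir":
        mtx = _find_one(path, ["matrix.mtx"])
        feats = _find_one(path, ["features.tsv", "genes.tsv"])
        bcs = _find_one(path, ["barcodes.tsv"])
        if mtx.suffix == ".gz":
            with gzip.open(mtx, "rb") as fh:
                m = spio.mmread(fh)
        else:
            m = spio.mmread(str(mtx))
        values = np.asarray(
            m.toarray() if sparse.issparse(m) else m, dtype=float
        )
        gene_ids = _read_id_column(feats)
        spot_ids = _read_id_column(bcs)
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        spot_ids = [str(s) for s in df.columns]
    else:
        raise ValueError(f"unknown expression format {format!r}")

    if transpose:
        values = values.T
        gene_ids, spot_ids = spot_ids, gene_ids
    return ExpressionMatrix(values, gene_ids, spot_ids)


def write_expression_mtx(matrix: ExpressionMatrix, directory) -> None:
    """Write an MTX triplet directory (matrix.mtx, features.tsv, barcodes.tsv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        str(directory / "matrix.mtx"), sparse.coo_matrix(matrix.values)
    )
    (directory / "features.tsv").write_text(
        "".join(f"{g}\n" for g in matrix.gene_ids)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(f"{s}\n" for s in matrix.spot_ids)
    )


# ---------------------------------------------------------------------------
# coordinates


def read_coordinates(path) -> SpotCoordinates:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"spot_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"coordinate file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return SpotCoordinates(
        [str(s) for s in df["spot_id"]],
        df["x"].to_numpy(float),
        df["y"].to_numpy(float),
    )


def write_coordinates(coords: SpotCoordinates, path) -> None:
    pd.DataFrame(
        {"spot_id": coords.spot_ids, "x": coords.x, "y": coords.y}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(path, format: str = "auto") -> GeneSetCollection:
    """Read marker sets from GMT or a two-column (cell_type, gene) TSV.

    GMT: name <tab> description <tab> gene1 <tab> gene2 ...  The description
    column is ignored. Within-set duplicates are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if format == "auto":
        format = "gmt" if path.suffix.lower() == ".gmt" else "two_column_tsv"

    sets: dict[str, list[str]] = {}
    with _open_maybe_gz(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if format == "gmt":
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs name, description "
                        f"and at least one gene"
                    )
                name, genes = fields[0], [g for g in fields[2:] if g]
            elif format == "two_column_tsv":
                if lineno == 1 and fields[:2] == ["cell_type", "gene"]:
                    continue
                if len(fields) < 2 or not fields[0] or not fields[1]:
                    raise ValueError(
                        f"{path}:{lineno}: expected two columns (cell_type, gene)"
                    )
                name, genes = fields[0], [fields[1]]
            else:
                raise ValueError(f"unknown gene-set format {format!r}")
            bucket = sets.setdefault(name, [])
            for g in genes:
                if g in bucket:
                    logger.warning(
                        "duplicate gene %r in set %r dropped", g, name
                    )
                else:
                    bucket.append(g)
    if not sets:
        raise ValueError(f"{path}: no gene sets parsed")
    for name, genes in sets.items():
        if not genes:
            raise ValueError(f"{path}: gene set {name!r} is empty")
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# annotation results


def write_annotation(result: AnnotationResult, path) -> None:
    """CSV with header spot_id,label,margin then one score column per type."""
    df = pd.DataFrame(
        {
            "spot_id": result.spot_ids,
            "label": result.labels,
            "margin": result.margin,
        }
    )
    for col in result.scores.columns:
        df[col] = result.scores[col].to_numpy()
    df.to_csv(path, index=False, float_format="%.12g")


def read_annotation(path) -> AnnotationResult:
    df = pd.read_csv(path)
    score_cols = [c for c in df.columns if c not in ("spot_id", "label", "margin")]
    scores = df[score_cols].copy()
    scores.index = df["spot_id"].astype(str)
    return AnnotationResult(
        [str(s) for s in df["spot_id"]],
        [str(l) for l in df["label"]],
        scores,
        df["margin"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# misc


def read_config(path) -> dict[str, str]:
    """Parse a key=value config file (one pair per line, # comments)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value")
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def match_genes(
    markers: list[str],
    gene_ids: list[str],
    case_insensitive: bool = False,
    set_name: str = "",
) -> list[str]:
    """Map marker symbols onto the matrix gene universe.

    Unmatched markers are logged and skipped; a set that loses all its genes
    raises, since scoring it would be meaningless.
    """
    if case_insensitive:
        lookup = {}
        for g in gene_ids:
            lookup.setdefault(g.casefold(), g)
        matched = [lookup[m.casefold()] for m in markers if m.casefold() in lookup]
        missing = [m for m in markers if m.casefold() not in lookup]
    else:
        universe = set(gene_ids)
        matched = [m for m in markers if m in universe]
        missing = [m for m in markers if m not in universe]
    if missing:
        logger.warning(
            "set %s: %d marker(s) not in matrix, skipped: %s",
            set_name or "<unnamed>",
            len(missing),
            missing[:10],
        )
    if not matched:
        raise ValueError(
            f"no marker of set {set_name or '<unnamed>'!r} found in the matrix; "
            f"missing: {missing}"
        )
    return matched
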