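"""Containers and IO for annotated expression matrices, gene sets and gene positions.

The pipeline exchanges four kinds of artifacts:

* ``.h5ad`` files (AnnData) for cell x gene expression — the normalized
  ``log2(1 + count/total * scale)`` layer in ``X``, raw counts in a layer
  named ``"counts"`` when CNV inference is intended;
* GMT files for named gene sets;
* a 4-column tab-delimited table (gene, chromosome, start, end) giving
  genomic positions for CNV inference;
* CSV for all per-cell outputs.

All downstream modules consume the in-memory containers defined here; no
other module touches the file system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import (
    CoordinateError,
    IndexingError,
    LabelError,
    NormalizationError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

COUNTS_LAYER = "counts"

__all__ = [
    "ExpressionDataset",
    "GeneSignature",
    "GenePositionTable",
    "read_expression",
    "write_expression",
    "validate_normalization",
    "read_gmt",
    "write_gmt",
    "read_gene_positions",
    "write_gene_positions",
]


def _dense(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)


@dataclass
class ExpressionDataset:
    """Annotated cells x genes expression matrix.

    ``matrix`` holds log2(1 + library-size-normalized counts); ``raw_counts``
    (optional, same shape and indexing) holds the untransformed counts needed
    for CNV inference. ``annotations`` carries at least one per-cell
    categorical column naming cell-type classes.
    """

    matrix: np.ndarray
    cell_ids: pd.Index
    gene_symbols: pd.Index
    annotations: pd.DataFrame
    dataset_name: str = "dataset"
    raw_counts: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.cell_ids = pd.Index([str(c).strip() for c in self.cell_ids])
        self.gene_symbols = pd.Index([str(g).strip() for g in self.gene_symbols])
        self.annotations = self.annotations.set_axis(self.cell_ids, axis=0)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells or len(self.gene_symbols) != n_genes:
            raise IndexingError("matrix shape does not match cell/gene index lengths")
        if self.cell_ids.has_duplicates:
            raise IndexingError("duplicate cell ids")
        if self.gene_symbols.has_duplicates:
            dupes = self.gene_symbols[self.gene_symbols.duplicated()].unique()[:5]
            raise IndexingError(f"duplicate gene symbols, e.g. {list(dupes)}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("matrix contains non-finite entries")
        if (self.matrix < 0).any():
            raise NormalizationError(
                "matrix contains negative entries; expected log2(1 + normalized "
                "count) values, which are nonnegative — is the input scaled?"
            )
        if self.raw_counts is not None:
            self.raw_counts = np.asarray(self.raw_counts)
            if self.raw_counts.shape != self.matrix.shape:
                raise IndexingError("raw_counts shape differs from matrix shape")
            if (self.raw_counts < 0).any():
                raise ValidationError("raw_counts contains negative entries")

    # -- convenience ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def labels(self, column: str) -> pd.Series:
        if column not in self.annotations.columns:
            raise LabelError(
                f"label column {column!r} not found in dataset "
                f"{self.dataset_name!r}; available: {list(self.annotations.columns)}"
            )
        col = self.annotations[column]
        if col.isna().any():
            raise LabelError(f"label column {column!r} has missing values")
        return col.astype(str)

    def subset_cells(self, mask: np.ndarray, suffix: str = "") -> "ExpressionDataset":
        return ExpressionDataset(
            matrix=self.matrix[mask],
            cell_ids=self.cell_ids[mask],
            gene_symbols=self.gene_symbols,
            annotations=self.annotations.loc[self.cell_ids[mask]].copy(),
            dataset_name=self.dataset_name + suffix,
            raw_counts=None if self.raw_counts is None else self.raw_counts[mask],
        )

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.matrix.astype(np.float64),
            obs=self.annotations.copy(),
            var=pd.DataFrame(index=self.gene_symbols),
        )
        adata.obs_names = self.cell_ids
        adata.uns["dataset_name"] = self.dataset_name
        if self.raw_counts is not None:
            adata.layers[COUNTS_LAYER] = self.raw_counts
        return adata

    @classmethod
    def from_anndata(
        cls, adata: ad.AnnData, label_columns: Sequence[str] | None = None,
        dataset_name: str | None = None,
    ) -> "ExpressionDataset":
        if label_columns:
            missing = [c for c in label_columns if c not in adata.obs.columns]
            if missing:
                raise LabelError(
                    f"label column(s) {missing} not present; "
                    f"available: {list(adata.obs.columns)}"
                )
        raw = None
        if COUNTS_LAYER in adata.layers:
            raw = _dense(adata.layers[COUNTS_LAYER])
        return cls(
            matrix=_dense(adata.X),
            cell_ids=pd.Index(adata.obs_names),
            gene_symbols=pd.Index(adata.var_names),
            annotations=adata.obs.copy(),
            dataset_name=dataset_name or str(adata.uns.get("dataset_name", "dataset")),
            raw_counts=raw,
        )


@dataclass(frozen=True)
class GeneSignature:
    """Named, directed gene list (e.g. tumor-up or tumor-depleted)."""

    name: str
    genes: tuple[str, ...]
    direction: str = "up_in_class"  # or "down_in_class"
    provenance: tuple = ()

    def __post_init__(self):
        genes = tuple(str(g).strip() for g in self.genes)
        seen, unique = set(), []
        for g in genes:
            if g not in seen:
                seen.add(g)
                unique.append(g)
        if len(unique) < len(genes):
            logger.warning(
                "signature %r: %d duplicate gene(s) dropped (first occurrence kept)",
                self.name, len(genes) - len(unique),
            )
        object.__setattr__(self, "genes", tuple(unique))
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if self.direction not in ("up_in_class", "down_in_class"):
            raise ValidationError(f"unknown direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def coverage(self, gene_symbols: pd.Index) -> float:
        """Fraction of the signature's genes present among ``gene_symbols``."""
        present = sum(g in gene_symbols for g in self.genes)
        return present / len(self.genes)


@dataclass
class GenePositionTable:
    """Genomic positions (1-based inclusive) for gene ordering in CNV inference."""

    table: pd.DataFrame  # columns: gene, chromosome, start, end

    def __post_init__(self):
        t = self.table
        required = ["gene", "chromosome", "start", "end"]
        if list(t.columns[:4]) != required:
            t = t.rename(columns=dict(zip(t.columns[:4], required)))
        t = t[required].copy()
        t["gene"] = t["gene"].astype(str).str.strip()
        t["chromosome"] = t["chromosome"].astype(str).str.strip()
        t["start"] = t["start"].astype(np.int64)
        t["end"] = t["end"].astype(np.int64)
        if t["gene"].duplicated().any():
            dupes = t.loc[t["gene"].duplicated(), "gene"].unique()[:5]
            raise IndexingError(f"duplicate gene symbols in position table: {list(dupes)}")
        bad = t["start"] > t["end"]
        if bad.any():
            g = t.loc[bad, "gene"].iloc[0]
            raise CoordinateError(f"gene {g!r} has start > end")
        # sort by chromosome token then start; only the ordering is consumed
        self.table = t.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    label_columns: Sequence[str] | None = None,
    dataset_name: str | None = None,
) -> ExpressionDataset:
    """Read an h5ad file into a validated :class:`ExpressionDataset`.

    Raises :class:`LabelError` when a requested annotation column is absent,
    :class:`NormalizationError` on negative matrix entries and
    :class:`IndexingError` on duplicate gene symbols.
    """
    path = Path(path)
    adata = ad.read_h5ad(path)
    name = dataset_name or str(adata.uns.get("dataset_name", path.stem))
    return ExpressionDataset.from_anndata(adata, label_columns, dataset_name=name)


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    dataset.to_anndata().write_h5ad(Path(path))


def validate_normalization(
    dataset: ExpressionDataset, min_genes: int = 5000
) -> list[str]:
    """Heuristic checks that the matrix is unscaled log2 data on the full gene set.

    Returns a (possibly empty) list of warning strings; never raises. A
    z-scaled matrix betrays itself through negative values or per-gene means
    near zero; a small gene count suggests pre-filtering (e.g. to highly
    variable genes), which corrupts rank-based scoring.
    """
    warnings: list[str] = []
    m = dataset.matrix
    gene_means = m.mean(axis=0)
    if (m < 0).any() or float(np.abs(gene_means).max()) < 1e-8:
        warnings.append(
            "scaled data: matrix looks z-scored (negative values or per-gene "
            "means ~ 0); provide unscaled log2(1 + normalized count) values"
        )
    if dataset.n_genes < min_genes:
        warnings.append(
            f"incomplete gene set: only {dataset.n_genes} genes (< {min_genes}); "
            "the matrix should contain the complete set of profiled genes, "
            "not a preselected subset"
        )
    for w in warnings:
        logger.warning("%s: %s", dataset.dataset_name, w)
    return warnings


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file (one set per line: name, description, genes...)."""
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} field(s); expected name, "
                    "description and at least one gene", line=lineno,
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            direction = "down_in_class" if name.strip().lower() == "normal" else "up_in_class"
            signatures.append(GeneSignature(name=name.strip(), genes=tuple(genes),
                                            direction=direction))
    return signatures


def write_gmt(signatures: Sequence[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.direction, *sig.genes]) + "\n")


def read_gene_positions(path: str | Path) -> GenePositionTable:
    """Read the 4-column tab-delimited (gene, chromosome, start, end) table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 4:
        raise ParseError(f"expected 4 tab-delimited columns, found {df.shape[1]}")
    return GenePositionTable(df)


def write_gene_positions(positions: GenePositionTable, path: str | Path) -> None:
    positions.table.to_csv(path, sep="\t", index=False)
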