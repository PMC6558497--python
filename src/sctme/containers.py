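"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`: a sparse genes x cells UMI
count matrix with aligned gene and cell metadata tables and an optional
normalized log layer. Genes are rows (matching the 10x triplet layout on
disk); cells are columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

GENE_META_COLUMNS = ("symbol", "chromosome", "position", "mito")
CELL_META_COLUMNS = ("barcode", "patient", "tissue")
TISSUES = ("tumor", "normal")


class FormatError(ValueError):
    """Raised when on-disk inputs violate the expected layout."""


@dataclass
class ExpressionMatrix:
    """Sparse UMI counts (genes x cells) with aligned metadata.

    Parameters
    ----------
    counts
        Nonnegative integer sparse matrix, genes in rows, cells in columns.
    gene_meta
        One row per gene; columns ``symbol``, ``chromosome``, ``position``
        (integer order along the chromosome) and boolean ``mito``.
    cell_meta
        One row per cell; columns ``barcode`` (unique), ``patient`` and
        ``tissue`` (``tumor`` or ``normal``).
    log_layer
        Optional dense genes x cells matrix of library-size-normalized
        log expression, filled by :func:`sctme.preprocess.normalize_log`.
    """

    counts: sp.csr_matrix
    gene_meta: pd.DataFrame
    cell_meta: pd.DataFrame
    log_layer: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_meta = self.gene_meta.reset_index(drop=True)
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        ng, nc = self.counts.shape
        if len(self.gene_meta) != ng:
            raise FormatError(
                f"gene_meta has {len(self.gene_meta)} rows for {ng} genes"
            )
        if len(self.cell_meta) != nc:
            raise FormatError(
                f"cell_meta has {len(self.cell_meta)} rows for {nc} cells"
            )
        for col in ("symbol",):
            if col not in self.gene_meta.columns:
                raise FormatError(f"gene_meta missing column {col!r}")
        if "barcode" not in self.cell_meta.columns:
            raise FormatError("cell_meta missing column 'barcode'")
        barcodes = self.cell_meta["barcode"]
        if barcodes.duplicated().any():
            dup = barcodes[barcodes.duplicated()].iloc[0]
            raise FormatError(f"duplicate cell barcode {dup!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if self.log_layer is not None and self.log_layer.shape != (ng, nc):
            raise FormatError("log_layer shape mismatch")

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_symbols(self) -> pd.Index:
        return pd.Index(self.gene_meta["symbol"])

    @property
    def barcodes(self) -> pd.Index:
        return pd.Index(self.cell_meta["barcode"])

    def gene_index(self, symbols: Iterable[str]) -> np.ndarray:
        """Row indices of ``symbols``; missing symbols are silently dropped."""
        lookup = pd.Index(self.gene_meta["symbol"])
        idx = lookup.get_indexer(list(symbols))
        return idx[idx >= 0]

    def total_counts(self) -> np.ndarray:
        """Total UMIs per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, index: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            counts=self.counts[:, index],
            gene_meta=self.gene_meta,
            cell_meta=self.cell_meta.iloc[index],
            log_layer=None if self.log_layer is None else self.log_layer[:, index],
        )

    def subset_genes(self, index: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ExpressionMatrix(
            counts=self.counts[index],
            gene_meta=self.gene_meta.iloc[index],
            cell_meta=self.cell_meta,
            log_layer=None if self.log_layer is None else self.log_layer[index],
        )

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            gene_meta=self.gene_meta.copy(),
            cell_meta=self.cell_meta.copy(),
            log_layer=None if self.log_layer is None else self.log_layer.copy(),
        )


def concatenate(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Concatenate cells of several matrices over the shared gene universe.

    Plain concatenation (no batch correction): genes are intersected by
    symbol in the order of the first matrix; cell metadata is stacked.
    """
    if not matrices:
        raise ValueError("nothing to concatenate")
    shared = pd.Index(matrices[0].gene_meta["symbol"])
    for m in matrices[1:]:
        shared = shared[shared.isin(set(m.gene_meta["symbol"]))]
    blocks = []
    for m in matrices:
        idx = pd.Index(m.gene_meta["symbol"]).get_indexer(shared)
        blocks.append(m.counts[idx])
    gene_meta = matrices[0].gene_meta.iloc[
        pd.Index(matrices[0].gene_meta["symbol"]).get_indexer(shared)
    ]
    cell_meta = pd.concat([m.cell_meta for m in matrices], ignore_index=True)
    return ExpressionMatrix(sp.hstack(blocks).tocsr(), gene_meta, cell_meta)


@dataclass
class QCReport:
    """Record of a quality-control pass over cells and genes."""

    n_cells_in: int
    n_cells_kept: int
    n_genes_in: int
    n_genes_kept: int
    thresholds: dict = field(default_factory=dict)
    per_cell: pd.DataFrame | None = None
    removal_reason: pd.Series | None = None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "n_cells_in": int(self.n_cells_in),
            "n_cells_kept": int(self.n_cells_kept),
            "n_genes_in": int(self.n_genes_in),
            "n_genes_kept": int(self.n_genes_kept),
            "thresholds": dict(self.thresholds),
            "warnings": list(self.warnings),
        }
        if self.removal_reason is not None:
            out["removal_reasons"] = (
                self.removal_reason.value_counts().to_dict()
            )
        return out
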