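"""Cell and gene quality filters.

Low-quality cells are discarded on two rules: fewer than ``min_genes``
detected genes, or a mitochondrial UMI fraction above ``max_mito``. Genes
are kept when expressed (count > 0) in at least ``min_cells`` cells. The
pipeline order is cells first, then genes, with the gene filter recomputed
on the surviving cells.

Boundary semantics: cells with exactly ``min_genes`` detected genes are
kept by default (``strict_min_genes=True`` switches to a strictly-greater
rule); cells at exactly ``max_mito`` are kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, QCReport

DEFAULT_MIN_GENES = 200
DEFAULT_MAX_MITO = 0.40
DEFAULT_MIN_CELLS = 5


def mito_fraction(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-cell fraction of UMIs from mitochondrial genes (0 for empty cells)."""
    mito = matrix.gene_meta["mito"].to_numpy(dtype=bool)
    total = matrix.total_counts().astype(float)
    mito_counts = np.asarray(matrix.counts[mito].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito_counts / np.maximum(total, 1e-300), 0.0)
    return frac


def filter_cells(
    matrix: ExpressionMatrix,
    min_genes: int = DEFAULT_MIN_GENES,
    max_mito: float = DEFAULT_MAX_MITO,
    strict_min_genes: bool = False,
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop low-quality cells; return the filtered matrix and a QC report.

    Each removed cell is attributed to the first failing rule
    (``low_genes`` before ``high_mito``).
    """
    if min_genes < 0 or not (0.0 <= max_mito <= 1.0):
        raise ValueError("thresholds out of range")
    detected = matrix.detected_genes()
    mito = mito_fraction(matrix)
    if strict_min_genes:
        pass_genes = detected > min_genes
    else:
        pass_genes = detected >= min_genes
    pass_mito = mito <= max_mito
    keep = pass_genes & pass_mito

    reason = np.full(matrix.n_cells, "kept", dtype=object)
    reason[~pass_genes] = "low_genes"
    reason[pass_genes & ~pass_mito] = "high_mito"
    per_cell = pd.DataFrame(
        {
            "barcode": matrix.cell_meta["barcode"].to_numpy(),
            "detected_genes": detected,
            "total_umis": matrix.total_counts(),
            "mito_fraction": mito,
            "kept": keep,
        }
    )
    report = QCReport(
        n_cells_in=matrix.n_cells,
        n_cells_kept=int(keep.sum()),
        n_genes_in=matrix.n_genes,
        n_genes_kept=matrix.n_genes,
        thresholds={
            "min_genes": min_genes,
            "max_mito": max_mito,
            "strict_min_genes": strict_min_genes,
        },
        per_cell=per_cell,
        removal_reason=pd.Series(reason[~keep], name="reason"),
    )
    if not keep.any():
        report.warnings.append("all cells removed by QC")
    return matrix.subset_cells(keep), report


def filter_genes(matrix: ExpressionMatrix, min_cells: int = DEFAULT_MIN_CELLS) -> ExpressionMatrix:
    """Keep genes expressed (count > 0) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be nonnegative")
    n_expressing = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    return matrix.subset_genes(n_expressing >= min_cells)


def run_qc(
    matrix: ExpressionMatrix,
    min_genes: int = DEFAULT_MIN_GENES,
    max_mito: float = DEFAULT_MAX_MITO,
    min_cells: int = DEFAULT_MIN_CELLS,
    strict_min_genes: bool = False,
) -> tuple[ExpressionMatrix, QCReport]:
    """Cell filter then gene filter; report records both steps."""
    filtered, report = filter_cells(matrix, min_genes, max_mito, strict_min_genes)
    filtered = filter_genes(filtered, min_cells)
    report.n_genes_kept = filtered.n_genes
    report.thresholds["min_cells"] = min_cells
    return filtered, report
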