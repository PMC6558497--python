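"""Epithelial subset splitting by ligand expression, and subset DE.

Subset 1 collects the epithelial clusters in which every ligand of a given
set (e.g. SFTPA1, ICAM1, CTGF, CYR61) is detected in at least a fraction of
the cluster's cells (default 25%); subset 2 is the remaining epithelial
cells. Tissue composition is reported per subset, and a negative-binomial
differential-expression comparison between the subsets flags genes at
|log2FC| > 1 and adjusted p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

DEFAULT_DETECTION_FRACTION = 0.25
DEFAULT_LFC_CUT = 1.0
DEFAULT_Q_CUT = 0.01


@dataclass
class SubsetComparison:
    subset: np.ndarray  # 1 or 2 per epithelial cell (local order of `cells`)
    cells: np.ndarray  # epithelial cell indices into the matrix
    qualifying_clusters: list
    tissue_fractions: pd.DataFrame  # subsets x tissues, rows sum to 1
    de: pd.DataFrame | None = None
    up_in_subset1: list = field(default_factory=list)
    down_in_subset1: list = field(default_factory=list)


def split_subsets(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    epithelial_clusters: list,
    ligand_set: list,
    detection_fraction: float = DEFAULT_DETECTION_FRACTION,
) -> SubsetComparison:
    """Partition epithelial cells by cluster-level ligand expression.

    A cluster qualifies for subset 1 when every ligand is detected
    (count > 0) in at least ``detection_fraction`` of its cells (a cluster
    at exactly the threshold qualifies).
    """
    if not ligand_set:
        raise ValueError("ligand_set must be nonempty")
    labels = np.asarray(labels)
    cells = np.flatnonzero(np.isin(labels, epithelial_clusters))
    lig_rows = matrix.gene_index(ligand_set)
    if lig_rows.size < len(set(ligand_set)):
        warnings.warn("some ligands absent from the matrix")
    expr = (matrix.counts[lig_rows] > 0).toarray()

    qualifying = []
    for cl in epithelial_clusters:
        members = np.flatnonzero(labels == cl)
        if members.size == 0:
            continue
        frac = expr[:, members].mean(axis=1)
        if lig_rows.size and np.all(frac >= detection_fraction):
            qualifying.append(cl)
    if not qualifying:
        warnings.warn("no epithelial cluster expresses all ligands; subset 1 empty")
    subset = np.where(np.isin(labels[cells], qualifying), 1, 2)

    tissues = matrix.cell_meta["tissue"].to_numpy()[cells]
    frames = []
    for s in (1, 2):
        t = pd.Series(tissues[subset == s])
        frac = t.value_counts(normalize=True) if len(t) else pd.Series(dtype=float)
        frames.append(frac.rename(f"subset{s}"))
    tissue_fractions = pd.concat(frames, axis=1).T.fillna(0.0)
    return SubsetComparison(
        subset=subset,
        cells=cells,
        qualifying_clusters=qualifying,
        tissue_fractions=tissue_fractions,
    )


def subset_de(
    matrix: ExpressionMatrix,
    comparison: SubsetComparison,
    lfc_cut: float = DEFAULT_LFC_CUT,
    q_cut: float = DEFAULT_Q_CUT,
    min_cells: int = 10,
) -> SubsetComparison:
    """NB DE of subset 1 vs subset 2; fills the significant gene lists."""
    from .annotate import de_test_nb

    cells1 = comparison.cells[comparison.subset == 1]
    cells2 = comparison.cells[comparison.subset == 2]
    if cells1.size < min_cells or cells2.size < min_cells:
        raise ValueError(
            f"subsets too small for DE ({cells1.size} vs {cells2.size} cells)"
        )
    de = de_test_nb(matrix, cells1, cells2)
    table = de.table.dropna(subset=["pvalue"])
    sig = table[(table["padj"] < q_cut) & (table["log2fc"].abs() > lfc_cut)]
    comparison.de = de.table
    comparison.up_in_subset1 = sig[sig["log2fc"] > 0].index.tolist()
    comparison.down_in_subset1 = sig[sig["log2fc"] < 0].index.tolist()
    return comparison
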