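"""Cluster annotation by marker enrichment scores over pairwise NB tests.

The score of marker set G_t in cluster i is

    C_i(G_t) = sum_{j != i} C_ij(G_t)
    C_ij(G_t) = sum of log2 fold changes FC_ij(g) over markers g in G_t
                whose BH-adjusted p-value in the i-vs-j NB test is < alpha

The sum is signed as written; pass ``positive_only=True`` to restrict to
markers elevated in cluster i. Each cluster is assigned the type with the
maximal score; ties are flagged ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .nbstats import bh_adjust, lrt_groups, size_factors
from .preprocess import Clustering

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: Minimal built-in marker table: the myeloid/DC markers used to identify
#: monocyte and dendritic-cell clusters. Real analyses extend this with a
#: full per-type marker table.
BUILTIN_MARKERS = {
    "CD14+ monocyte": ["CD14", "FCGR3A"],
    "CD1c+ DC": ["CD1C"],
    "CD141+ DC": ["THBD"],
}

#: The twelve populations resolved in paired tumor/normal NSCLC tissue.
POPULATIONS = [
    "fibroblasts", "CD14+ monocytes", "CD14- monocytes", "M1 macrophages",
    "M2 macrophages", "CD1c+ DC", "CD141+ DC", "natural killer cells",
    "B cells", "T-helper cells", "CD8+ T cells", "other T cells",
]


@dataclass
class MarkerCollection:
    """Mapping cell type -> marker gene set."""

    sets: dict

    def __post_init__(self) -> None:
        for t, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty marker set for type {t!r}")
            self.sets[t] = list(dict.fromkeys(genes))

    @property
    def types(self) -> list:
        return list(self.sets)

    def restrict_to(self, symbols: pd.Index) -> "MarkerCollection":
        """Drop marker genes absent from the matrix (logged)."""
        out = {}
        have = set(symbols)
        for t, genes in self.sets.items():
            kept = [g for g in genes if g in have]
            missing = set(genes) - set(kept)
            if missing:
                logger.warning("markers for %s not in matrix: %s", t, sorted(missing))
            if kept:
                out[t] = kept
        return MarkerCollection(out)


@dataclass
class PairwiseDEResult:
    """NB differential-expression table for one ordered cluster pair."""

    pair: tuple  # (i, j)
    table: pd.DataFrame  # index: gene symbol; log2fc, pvalue, padj

    def reversed(self) -> "PairwiseDEResult":
        t = self.table.copy()
        t["log2fc"] = -t["log2fc"]
        return PairwiseDEResult(pair=(self.pair[1], self.pair[0]), table=t)


@dataclass
class TypeScoreTable:
    """Cluster x type score matrix with per-pair provenance."""

    scores: pd.DataFrame  # clusters x types
    assignment: pd.Series  # winning type per cluster
    margin: pd.Series  # score gap to the runner-up
    ambiguous: pd.Series  # tie flag per cluster
    pair_scores: dict = field(default_factory=dict)  # (i, j, type) -> C_ij(G_t)


def markers_from_gmt(path) -> MarkerCollection:
    """Load a marker collection from a GMT file (one set per cell type)."""
    from .genesets import load_gmt

    return MarkerCollection(dict(load_gmt(path).sets))


def markers_from_tsv(path) -> MarkerCollection:
    """Load a marker collection from a two-column (type, gene) TSV."""
    from .io import load_marker_table

    return MarkerCollection(load_marker_table(path))


def de_test_nb(
    matrix: ExpressionMatrix,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    pseudocount: float = 1.0,
) -> PairwiseDEResult:
    """Per-gene NB LRT between two cell groups with library-size offsets.

    log2 fold change is computed from the fitted group means on the
    typical-cell count scale with a pseudocount of ``pseudocount``. Genes
    all-zero in both groups are excluded from testing and from the BH
    denominator.
    """
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.size < 3 or cells_b.size < 3:
        raise ValueError("each group needs at least 3 cells")
    cols = np.concatenate([cells_a, cells_b])
    y = np.asarray(matrix.counts[:, cols].todense(), dtype=float)
    totals = matrix.total_counts()[cols]
    s = size_factors(totals)
    groups = np.repeat([0, 1], [cells_a.size, cells_b.size])
    res = lrt_groups(y, s, groups)
    # rates per 10,000 UMIs (the normalization scale); pseudocount on that
    # mean scale
    med = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    per10k = 1e4 / med
    res["rate_0"] *= per10k
    res["rate_1"] *= per10k
    log2fc = np.log2(res["rate_0"] + pseudocount) - np.log2(res["rate_1"] + pseudocount)
    table = pd.DataFrame(
        {
            "log2fc": log2fc.to_numpy(),
            "pvalue": res["pvalue"].to_numpy(),
            "padj": bh_adjust(res["pvalue"].to_numpy()),
            "rate_a": res["rate_0"].to_numpy(),
            "rate_b": res["rate_1"].to_numpy(),
        },
        index=pd.Index(matrix.gene_meta["symbol"], name="gene"),
    )
    return PairwiseDEResult(pair=(0, 1), table=table)


def pair_score(
    de: PairwiseDEResult, markers: list, alpha: float = DEFAULT_ALPHA,
    positive_only: bool = False,
) -> float:
    """C_ij(G_t): signed sum of significant marker log2 fold changes."""
    table = de.table
    present = [g for g in markers if g in table.index]
    missing = set(markers) - set(present)
    if missing:
        logger.debug("markers absent from DE table: %s", sorted(missing))
    if not present:
        return 0.0
    sub = table.loc[present]
    sig = sub["padj"] < alpha
    fc = sub.loc[sig, "log2fc"]
    if positive_only:
        fc = fc[fc > 0]
    return float(fc.sum())


def cluster_type_scores(
    matrix: ExpressionMatrix,
    clustering: Clustering | np.ndarray,
    markers: MarkerCollection | dict,
    alpha: float = DEFAULT_ALPHA,
    positive_only: bool = False,
) -> TypeScoreTable:
    """Score every cluster against every marker set and assign identities.

    Computes the N(N-1)/2 unordered pairwise NB tests (the reverse pair is
    the exact negation) and assembles C_i(G_t) = sum_j C_ij(G_t).
    """
    labels = clustering.labels if isinstance(clustering, Clustering) else np.asarray(clustering)
    if isinstance(markers, dict):
        markers = MarkerCollection(dict(markers))
    markers = markers.restrict_to(matrix.gene_symbols)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("enrichment score undefined with a single cluster")

    de_cache: dict[tuple, PairwiseDEResult] = {}
    for a_pos, i in enumerate(clusters):
        for j in clusters[a_pos + 1 :]:
            de = de_test_nb(matrix, np.flatnonzero(labels == i), np.flatnonzero(labels == j))
            de_cache[(i, j)] = de
            de_cache[(j, i)] = de.reversed()

    types = markers.types
    scores = pd.DataFrame(0.0, index=pd.Index(clusters, name="cluster"), columns=types)
    pair_scores = {}
    for i in clusters:
        for j in clusters:
            if i == j:
                continue
            for t in types:
                cij = pair_score(de_cache[(i, j)], markers.sets[t], alpha, positive_only)
                pair_scores[(i, j, t)] = cij
                scores.loc[i, t] += cij

    assignment, margin, ambiguous = {}, {}, {}
    for i in clusters:
        row = scores.loc[i].sort_values(ascending=False)
        assignment[i] = row.index[0]
        margin[i] = float(row.iloc[0] - row.iloc[1]) if len(row) > 1 else np.inf
        ambiguous[i] = bool(len(row) > 1 and np.isclose(row.iloc[0], row.iloc[1]))
        if ambiguous[i]:
            # tie-break on the best single pair contribution, then name
            tied = row.index[np.isclose(row.to_numpy(), row.iloc[0])]
            best = sorted(
                tied,
                key=lambda t: (-max(pair_scores[(i, j, t)] for j in clusters if j != i), t),
            )
            assignment[i] = best[0]
    return TypeScoreTable(
        scores=scores,
        assignment=pd.Series(assignment, name="type"),
        margin=pd.Series(margin, name="margin"),
        ambiguous=pd.Series(ambiguous, name="ambiguous"),
        pair_scores=pair_scores,
    )
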