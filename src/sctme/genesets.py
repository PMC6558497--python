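"""Hypergeometric gene-set enrichment against GMT collections.

One-sided over-representation: with a universe of N genes of which K belong
to the set and a query of n genes with overlap k, p = P(X >= k) under
Hypergeometric(N, K, n). P-values are BH-corrected across all sets of the
collection; adjusted p < 0.05 is the significance convention. The reported
``plot_score`` column is -log10(adjusted p)/10, the bar-plot axis transform
used for presentation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .nbstats import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict  # name -> list of genes
    descriptions: dict

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {name!r}")

    @property
    def names(self) -> list:
        return list(self.sets)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB genes...).

    Duplicate set names and empty gene lists are errors; duplicate genes
    within a set are deduplicated and logged.
    """
    sets: dict = {}
    descriptions: dict = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {ln}: expected name, description, genes")
        name, desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"GMT line {ln}: set {name!r} has no genes")
        if name in sets:
            raise ValueError(f"duplicate set name {name!r} (line {ln})")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            logger.info("set %s: %d duplicate genes removed", name, len(genes) - len(deduped))
        sets[name] = deduped
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def hypergeom_enrich(
    query: list,
    collection: GeneSetCollection,
    universe: list,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set, BH-corrected.

    Query genes outside the universe are dropped (logged); set members are
    intersected with the universe before counting. Results are sorted by
    adjusted p.
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    q = [g for g in dict.fromkeys(query) if g in uni_set]
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("%d query genes outside the universe dropped", dropped)
    if not q:
        warnings.warn("empty query after intersecting with the universe")
        return pd.DataFrame(
            columns=["set", "N", "K", "n", "k", "pvalue", "padj", "significant", "plot_score"]
        )
    N, n = len(uni), len(q)
    qset = set(q)
    rows = []
    for name, genes in collection.sets.items():
        members = uni_set & set(genes)
        K = len(members)
        k = len(qset & members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "N": N, "K": K, "n": n, "k": k, "pvalue": p})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    out["significant"] = out["padj"] < alpha
    out["plot_score"] = -np.log10(np.maximum(out["padj"], 1e-300)) / 10.0
    return out.sort_values(["padj", "pvalue"], kind="stable").reset_index(drop=True)
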