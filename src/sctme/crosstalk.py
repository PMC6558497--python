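"""Ligand-receptor crosstalk between annotated cell types.

The interaction rule is the single-cell expression criterion: a database
pair (L, R) yields a potential interaction from type A to type B whenever
at least ``min_count`` cells of A express the ligand (count > 0) and at
least ``min_count`` cells of B express the receptor. ``min_count`` defaults
to 1, i.e. a single expressing cell on each side suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class LRDatabase:
    pairs: pd.DataFrame  # columns ligand, receptor (+ optional source)

    def __post_init__(self) -> None:
        if not {"ligand", "receptor"}.issubset(self.pairs.columns):
            raise ValueError("LR table needs 'ligand' and 'receptor' columns")
        before = len(self.pairs)
        self.pairs = self.pairs.drop_duplicates(["ligand", "receptor"]).reset_index(drop=True)
        if len(self.pairs) < before:
            logger.info("%d duplicate LR pairs dropped", before - len(self.pairs))
        self.pairs["self_pair"] = self.pairs["ligand"] == self.pairs["receptor"]

    @property
    def n_ligands(self) -> int:
        return self.pairs["ligand"].nunique()

    @property
    def n_receptors(self) -> int:
        return self.pairs["receptor"].nunique()

    def __len__(self) -> int:
        return len(self.pairs)


def load_lr_pairs(path: str | Path) -> LRDatabase:
    """TSV with ligand and receptor columns -> deduplicated database."""
    df = pd.read_csv(path, sep="\t")
    missing = {"ligand", "receptor"} - set(df.columns)
    if missing:
        raise ValueError(f"LR pair file missing columns: {sorted(missing)}")
    db = LRDatabase(df[[c for c in df.columns]])
    logger.info(
        "loaded %d pairs (%d ligands, %d receptors)", len(db), db.n_ligands, db.n_receptors
    )
    return db


def infer_interactions(
    matrix: ExpressionMatrix,
    cell_types: np.ndarray,
    db: LRDatabase,
    min_count: int = 1,
    min_fraction: float = 0.0,
) -> pd.DataFrame:
    """Enumerate potential interactions for every ordered type pair.

    Returns one record per (source, target, ligand, receptor) satisfying
    the expression rule, with expressing-cell counts and fractions.
    ``min_fraction`` optionally additionally requires the expressing-cell
    fraction on each side to reach a threshold (0 = single-cell rule).
    """
    cell_types = np.asarray(cell_types)
    types = [t for t in pd.unique(cell_types)]
    sizes = {t: int((cell_types == t).sum()) for t in types}
    types = [t for t in types if sizes[t] > 0]

    symbols = pd.Index(matrix.gene_meta["symbol"])
    genes = pd.unique(pd.concat([db.pairs["ligand"], db.pairs["receptor"]]))
    rows = symbols.get_indexer(genes)
    present = {g: r for g, r in zip(genes, rows) if r >= 0}

    # expressing-cell counts per (gene, type)
    expr = (matrix.counts > 0).tocsr()
    counts: dict = {}
    for t in types:
        cols = np.flatnonzero(cell_types == t)
        per_gene = np.asarray(expr[:, cols].sum(axis=1)).ravel()
        counts[t] = per_gene

    records = []
    for _, row in db.pairs.iterrows():
        lig, rec = row["ligand"], row["receptor"]
        li, ri = present.get(lig), present.get(rec)
        if li is None or ri is None:
            continue
        for a in types:
            n_lig = int(counts[a][li])
            if n_lig < min_count or n_lig < min_fraction * sizes[a]:
                continue
            for b in types:
                n_rec = int(counts[b][ri])
                if n_rec < min_count or n_rec < min_fraction * sizes[b]:
                    continue
                records.append(
                    {
                        "source": a,
                        "target": b,
                        "ligand": lig,
                        "receptor": rec,
                        "n_source_expressing": n_lig,
                        "n_target_expressing": n_rec,
                        "frac_source": n_lig / sizes[a],
                        "frac_target": n_rec / sizes[b],
                    }
                )
    return pd.DataFrame(
        records,
        columns=[
            "source", "target", "ligand", "receptor",
            "n_source_expressing", "n_target_expressing",
            "frac_source", "frac_target",
        ],
    )


def ligand_source_summary(
    table: pd.DataFrame, receptor_set: list, target_types: list
) -> pd.DataFrame:
    """Distinct-ligand counts per source type for receptors of interest.

    Restricts the interaction table to records whose receptor is in
    ``receptor_set`` and whose target type is in ``target_types``, then
    counts distinct ligands per source type; percentages are over the union
    of ligands across sources.
    """
    if not receptor_set:
        raise ValueError("receptor_set must be nonempty")
    sub = table[
        table["receptor"].isin(receptor_set) & table["target"].isin(target_types)
    ]
    if sub.empty:
        logger.warning("no interactions match the receptor/target restriction")
        return pd.DataFrame(columns=["source", "n_ligands", "percent"])
    total = sub["ligand"].nunique()
    out = (
        sub.groupby("source")["ligand"]
        .nunique()
        .rename("n_ligands")
        .reset_index()
        .sort_values("n_ligands", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    out["percent"] = 100.0 * out["n_ligands"] / total
    return out
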