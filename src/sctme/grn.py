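"""Tree-ensemble co-regulatory network inference (GENIE3-style).

Each target gene's expression is regressed on the candidate regulators with
a randomized-tree ensemble; the importance of regulator r for target t is
the normalized total variance reduction attributed to r, and the directed
edge weight r -> t. A regulator's hub score is the sum of its outgoing
importances; the hub is the maximal-score regulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryNetwork:
    edges: pd.DataFrame  # regulator, target, importance (normalized per target)
    regulators: list
    hub_scores: pd.Series

    @property
    def hub(self) -> str:
        return str(self.hub_scores.idxmax())


def infer_grn(
    matrix: ExpressionMatrix,
    targets: list,
    candidate_regulators: list,
    cells: np.ndarray | None = None,
    n_trees: int = 500,
    max_features: str | float = "sqrt",
    seed: int = 0,
) -> RegulatoryNetwork:
    """Fit one ExtraTrees ensemble per target on regulator log expression.

    A gene may appear in both lists but never regresses on itself; constant
    targets are skipped with a log message. Importances are nonnegative and
    sum to 1 per target (ExtraTrees normalization).
    """
    from sklearn.ensemble import ExtraTreesRegressor

    if matrix.log_layer is None:
        raise ValueError("log layer missing; call normalize_log first")
    if cells is None:
        cells = np.arange(matrix.n_cells)
    cells = np.asarray(cells)
    if cells.size < 50:
        raise ValueError("need at least 50 cells for network inference")

    symbols = pd.Index(matrix.gene_meta["symbol"])
    reg_idx = {g: symbols.get_loc(g) for g in candidate_regulators if g in symbols}
    regulators = list(reg_idx)
    if not regulators:
        raise ValueError("no candidate regulators present in the matrix")
    R = matrix.log_layer[np.ix_(list(reg_idx.values()), cells)].T  # cells x regs

    rng = np.random.default_rng(seed)
    records = []
    for tg in targets:
        if tg not in symbols:
            logger.info("target %s absent from matrix; skipped", tg)
            continue
        y = matrix.log_layer[symbols.get_loc(tg), cells]
        if np.ptp(y) == 0:
            logger.info("target %s constant; skipped", tg)
            continue
        use = [i for i, r in enumerate(regulators) if r != tg]
        model = ExtraTreesRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(R[:, use], y)
        imp = model.feature_importances_
        for i, w in zip(use, imp):
            records.append({"regulator": regulators[i], "target": tg, "importance": float(w)})
    edges = pd.DataFrame(records, columns=["regulator", "target", "importance"])
    hub_scores = (
        edges.groupby("regulator")["importance"].sum()
        if len(edges)
        else pd.Series(dtype=float)
    )
    hub_scores = hub_scores.reindex(regulators, fill_value=0.0)
    return RegulatoryNetwork(edges=edges, regulators=regulators, hub_scores=hub_scores)


def to_networkx(network: RegulatoryNetwork, min_importance: float = 0.0):
    """Directed weighted graph of edges above ``min_importance``."""
    import networkx as nx

    g = nx.DiGraph()
    for _, row in network.edges.iterrows():
        if row["importance"] >= min_importance:
            g.add_edge(row["regulator"], row["target"], weight=row["importance"])
    return g
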