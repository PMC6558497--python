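"""Pseudotime trajectories for myeloid differentiation analysis.

Cells are ordered along a principal tree: PCA to two dimensions on a set of
ordering genes (per-cluster differential genes), k-means centroids, a
minimum spanning tree over the centroids, and projection of each cell onto
its nearest tree edge. Tree segments between branch/leaf nodes define
states. Rooting is two-pass: the state most enriched for a designated
root population (by default CD14+ monocytes from normal tissue) is chosen
first; pseudotime is then recomputed from the root end as arc length along
a principal curve (first principal component ordering smoothed through the
embedding), which is robust to the zigzag a raw centroid tree inherits
from embedding noise. The tree supplies topology — states, branch points,
leaf fates; the curve supplies the ordering.

Two gene-level tests follow the trajectory: a state-factor NB LRT
(``~state`` vs ``~1``) and a smooth pseudotime NB LRT (natural cubic spline
of pseudotime, df=3, vs intercept), both BH-corrected; transition-state
genes pass raw p < 0.005 and FDR < 0.05 and get a direction from the sign
of the fitted trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist
from scipy.stats import chi2, spearmanr

from .containers import ExpressionMatrix
from .nbstats import bh_adjust, estimate_dispersion, lrt_groups, size_factors

DEFAULT_P_CUT = 0.005
DEFAULT_Q_CUT = 0.05
AMBIGUOUS_RHO = 0.2


@dataclass
class Trajectory:
    """Principal-tree ordering of a cell subset."""

    cells: np.ndarray  # indices into the source matrix
    pseudotime: np.ndarray  # per participating cell, root = 0
    state: np.ndarray  # state id per participating cell
    node_coords: np.ndarray  # k x 2 centroid positions
    edges: list  # (u, v, length)
    edge_state: dict  # (u, v) -> state id
    root_state: int
    root_node: int
    leaf_states: list
    state_path_nodes: dict  # state id -> ordered node list
    coords: np.ndarray  # cells x 2 PCA coordinates

    def path_states(self, leaf_state: int) -> list:
        """States on the root -> leaf_state path."""
        return self._paths[leaf_state]

    _paths: dict = field(default_factory=dict, repr=False)

    def path_cell_mask(self, leaf_state: int, min_branch_frac: float = 0.1) -> np.ndarray:
        """Cells on the root -> ``leaf_state`` path.

        A cell is excluded only when it sits on a *substantial* alternative
        branch: the exclusive states of another leaf holding at least
        ``min_branch_frac`` of the cells AND spanning at least 30% of the
        pseudotime range (a genuine fate diverges early and runs long).
        Cells on small noise spurs keep their place on the main path.
        """
        n = self.state.size
        on_path = set(self.path_states(leaf_state))
        excluded = np.zeros(n, dtype=bool)
        total_span = float(np.ptp(self.pseudotime)) or 1.0
        for other in self.leaf_states:
            if other == leaf_state:
                continue
            exclusive = set(self.path_states(other)) - on_path
            if not exclusive:
                continue
            member = np.isin(self.state, list(exclusive))
            if member.sum() < min_branch_frac * n:
                continue
            span = float(np.ptp(self.pseudotime[member]))
            if span >= 0.3 * total_span:
                excluded |= member
        return ~excluded


@dataclass
class TransitionGeneResult:
    gene: str
    lrt: float
    pvalue: float
    qvalue: float
    direction: str  # up / down / ambiguous
    rho: float
    fitted: np.ndarray | None = None


def ordering_genes(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    cells: np.ndarray | None = None,
    alpha: float = 0.05,
    top_per_cluster: int = 50,
    min_genes: int = 10,
) -> list:
    """Union of per-cluster one-vs-rest NB differential genes.

    Each cluster contributes up to ``top_per_cluster`` genes with
    BH-adjusted p < alpha, ranked by p, skipping genes an earlier cluster
    already contributed — so the budget scales with the cluster count even
    when the one-vs-rest tests mirror each other (two clusters).
    """
    from .annotate import de_test_nb

    labels = np.asarray(labels)
    if cells is None:
        cells = np.arange(matrix.n_cells)
    cells = np.asarray(cells)
    sub = matrix.subset_cells(cells)
    sub_labels = labels[cells]
    selected: list = []
    for cl in np.unique(sub_labels):
        inside = np.flatnonzero(sub_labels == cl)
        outside = np.flatnonzero(sub_labels != cl)
        if inside.size < 3 or outside.size < 3:
            continue
        de = de_test_nb(sub, inside, outside)
        t = de.table.dropna(subset=["pvalue"])
        hits = t[t["padj"] < alpha].sort_values("pvalue", kind="stable")
        new = [g for g in hits.index if g not in selected]
        selected.extend(new[:top_per_cluster])
    out = list(dict.fromkeys(selected))
    if len(out) < min_genes:
        raise ValueError(
            f"only {len(out)} ordering genes found; lower the stringency or "
            "check that the clusters differ"
        )
    return out


def _principal_curve_pt(
    coords: np.ndarray,
    root_local: np.ndarray,
    span: float = 0.25,
    max_vertices: int = 500,
) -> np.ndarray:
    """Arc-length pseudotime along a smoothed principal curve.

    The curve is the rolling mean of the coordinates ordered by the first
    principal component (oriented so root cells sit early); every cell is
    projected onto the polyline and takes its arc-length position.
    """
    n = coords.shape[0]
    center = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(center, full_matrices=False)
    g = center @ vt[0]
    if root_local.any() and g[root_local].mean() > g.mean():
        g = -g
    w = max(int(span * n), 7)
    order = np.argsort(g, kind="stable")
    sm = (
        pd.DataFrame(coords[order])
        .rolling(w, center=True, min_periods=max(w // 3, 4))
        .mean()
        .to_numpy()
    )
    sm = sm[~np.isnan(sm).any(axis=1)]
    if len(sm) > max_vertices:
        sm = sm[:: int(np.ceil(len(sm) / max_vertices))]
    if len(sm) < 2:
        return g - g.min()
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(sm, axis=0), axis=1))]
    )
    if arc[-1] <= 0:
        return g - g.min()
    a = sm[:-1]
    ab = np.diff(sm, axis=0)
    seg_len2 = np.maximum((ab * ab).sum(axis=1), 1e-12)
    pt = np.empty(n)
    for i in range(n):
        t = np.clip(((coords[i] - a) * ab).sum(axis=1) / seg_len2, 0.0, 1.0)
        d2 = ((coords[i] - (a + t[:, None] * ab)) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        pt[i] = arc[j] + t[j] * (arc[j + 1] - arc[j])
    return pt - pt.min()


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Project points p (n x 2) onto segment a-b; returns (t in [0,1], dist)."""
    ab = b - a
    denom = max(float(ab @ ab), 1e-12)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a[None, :] + t[:, None] * ab[None, :]
    dist = np.linalg.norm(p - proj, axis=1)
    return t, dist


def learn_trajectory(
    matrix: ExpressionMatrix,
    genes: list,
    cells: np.ndarray | None = None,
    root_mask: np.ndarray | None = None,
    seed: int = 0,
) -> Trajectory:
    """Fit the principal tree and order cells from the root.

    ``root_mask`` flags (over all matrix cells) the population anchoring
    the root, e.g. monocytes from normal tissue. The state with the highest
    root-cell enrichment becomes the root state; pseudotime is arc length
    from the root end along the principal curve of the embedding.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if matrix.log_layer is None:
        raise ValueError("log layer missing; call normalize_log first")
    if cells is None:
        cells = np.arange(matrix.n_cells)
    cells = np.asarray(cells)
    if root_mask is None or not np.asarray(root_mask)[cells].any():
        raise ValueError("root rule matches no participating cells")
    root_cells_local = np.flatnonzero(np.asarray(root_mask)[cells])

    idx = matrix.gene_index(genes)
    X = matrix.log_layer[np.ix_(idx, cells)].T  # cells x genes
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    coords = PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(X)

    n = coords.shape[0]
    k = int(max(np.sqrt(n) / 2, 10))
    k = min(k, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
    centroids = km.cluster_centers_

    dists = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dists).toarray()
    mst = np.maximum(mst, mst.T)
    edges = [
        (u, v, float(mst[u, v]))
        for u in range(k)
        for v in range(u + 1, k)
        if mst[u, v] > 0
    ]

    # project every cell to its nearest edge
    best_dist = np.full(n, np.inf)
    cell_edge = np.zeros(n, dtype=int)
    cell_t = np.zeros(n)
    for ei, (u, v, _) in enumerate(edges):
        t, d = _project_to_segment(coords, centroids[u], centroids[v])
        better = d < best_dist
        best_dist[better] = d[better]
        cell_edge[better] = ei
        cell_t[better] = t[better]

    # states: maximal degree-2 chains between branch/leaf nodes
    degree = np.zeros(k, dtype=int)
    adjacency: dict[int, list] = {u: [] for u in range(k)}
    for u, v, _ in edges:
        degree[u] += 1
        degree[v] += 1
        adjacency[u].append(v)
        adjacency[v].append(u)
    key_nodes = {u for u in range(k) if degree[u] != 2}
    edge_state: dict[tuple, int] = {}
    state_nodes: dict[int, list] = {}
    sid = 0
    visited = set()
    for start in sorted(key_nodes):
        for nxt in adjacency[start]:
            if (start, nxt) in visited:
                continue
            chain = [start, nxt]
            visited.add((start, nxt))
            visited.add((nxt, start))
            while chain[-1] not in key_nodes:
                prev, cur = chain[-2], chain[-1]
                nxt2 = [w for w in adjacency[cur] if w != prev][0]
                visited.add((cur, nxt2))
                visited.add((nxt2, cur))
                chain.append(nxt2)
            if chain[0] > chain[-1] and chain[-1] in key_nodes:
                pair = (min(chain[0], chain[-1]), max(chain[0], chain[-1]))
            for a, b in zip(chain[:-1], chain[1:]):
                edge_state[(min(a, b), max(a, b))] = sid
            state_nodes[sid] = chain
            sid += 1
    if not edge_state:  # single node / no edges
        edge_state[(0, 0)] = 0
        state_nodes[0] = [0]

    cell_state = np.array(
        [
            edge_state.get(
                (min(edges[e][0], edges[e][1]), max(edges[e][0], edges[e][1])), 0
            )
            for e in cell_edge
        ]
    )

    # first pass: root state = state most enriched for root-rule cells.
    # Enrichment weighs purity by mass (count x fraction) so a noise spur of
    # a few pure cells cannot outvote the true root segment.
    score = {}
    root_flag = np.zeros(n, dtype=bool)
    root_flag[root_cells_local] = True
    for s in state_nodes:
        members = cell_state == s
        k_root = int(root_flag[members].sum())
        score[s] = k_root * (k_root / members.sum()) if members.any() else 0.0
    root_state = max(score, key=score.get)

    # root node = extreme tip of the root state: prefer a tree leaf endpoint,
    # otherwise the endpoint farther from the rest of the tree
    chain = state_nodes[root_state]
    endpoints = [chain[0], chain[-1]]
    nodal = shortest_path(mst, method="D", directed=False)
    leaves = [e for e in endpoints if degree[e] <= 1]
    if leaves:
        root_node = leaves[0]
    else:
        root_node = max(endpoints, key=lambda e: nodal[e].sum())

    # second pass: pseudotime from the root end as principal-curve arc length
    pseudotime = _principal_curve_pt(coords, root_flag)

    leaf_states = sorted(
        {
            s
            for s, chain in state_nodes.items()
            if any(degree[e] <= 1 and e != root_node for e in (chain[0], chain[-1]))
        }
    )

    # root->leaf state paths via node shortest paths
    paths = {}
    for s in state_nodes:
        chain = state_nodes[s]
        far = max(chain, key=lambda e: nodal[root_node, e])
        _, pred = shortest_path(
            mst, method="D", directed=False, return_predecessors=True, indices=root_node
        )
        node_path = [far]
        while node_path[-1] != root_node and pred[node_path[-1]] >= 0:
            node_path.append(int(pred[node_path[-1]]))
        node_path.reverse()
        on_path = set()
        for a, b in zip(node_path[:-1], node_path[1:]):
            on_path.add(edge_state[(min(a, b), max(a, b))])
        on_path.add(s)
        on_path.add(root_state)
        paths[s] = sorted(on_path)

    traj = Trajectory(
        cells=cells,
        pseudotime=pseudotime,
        state=cell_state,
        node_coords=centroids,
        edges=edges,
        edge_state=edge_state,
        root_state=int(root_state),
        root_node=int(root_node),
        leaf_states=leaf_states,
        state_path_nodes=state_nodes,
        coords=coords,
    )
    traj._paths = paths
    return traj


def assign_fates(traj: Trajectory, cell_labels: np.ndarray, fate_label: str) -> dict:
    """Name the leaf states: the leaf richest in ``fate_label`` cells is AT1.

    ``cell_labels`` is over all matrix cells; returns {"AT1": state, "AT2": state or None}.
    """
    labels = np.asarray(cell_labels)[traj.cells]
    cand = [s for s in traj.leaf_states if s != traj.root_state] or traj.leaf_states
    frac = {
        s: (labels[traj.state == s] == fate_label).mean()
        if (traj.state == s).any()
        else 0.0
        for s in cand
    }
    order = sorted(frac, key=frac.get, reverse=True)
    return {"AT1": order[0], "AT2": order[1] if len(order) > 1 else None}


def de_by_state(
    matrix: ExpressionMatrix, traj: Trajectory, min_cells_per_state: int = 3
) -> pd.DataFrame:
    """NB LRT of the state factor (~state vs ~1) per gene, BH-corrected.

    States with fewer than ``min_cells_per_state`` cells are merged into the
    adjacent state nearer the root (flagged in the 'merged_states' attr).
    """
    state = traj.state.copy()
    merged = []
    for s in np.unique(state):
        if (state == s).sum() < min_cells_per_state:
            others = state[state != s]
            if others.size == 0:
                continue
            # merge into the state whose cells are nearest in pseudotime
            target = min(
                np.unique(others),
                key=lambda t: abs(
                    traj.pseudotime[state == t].mean()
                    - traj.pseudotime[state == s].mean()
                ),
            )
            state[state == s] = target
            merged.append((int(s), int(target)))
    if np.unique(state).size < 2:
        raise ValueError("need at least two states")
    y = np.asarray(matrix.counts[:, traj.cells].todense(), dtype=float)
    s_fac = size_factors(matrix.total_counts()[traj.cells])
    res = lrt_groups(y, s_fac, state)
    out = pd.DataFrame(
        {
            "gene": matrix.gene_meta["symbol"].to_numpy(),
            "lrt": res["lrt"],
            "pvalue": res["pvalue"],
            "qvalue": bh_adjust(res["pvalue"].to_numpy()),
        }
    )
    out.attrs["merged_states"] = merged
    return out


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (no intercept), knots at quantiles.

    Matches the construction of R's splines::ns: boundary knots at the data
    range, df-1 interior knots, linearity enforced beyond the boundaries.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None]
    probs = np.linspace(0, 1, df + 1)[1:-1]
    interior = np.quantile(x, probs)
    lo, hi = x.min(), x.max()
    knots = np.concatenate([[lo], interior, [hi]])

    def d(k: float) -> np.ndarray:
        num = np.maximum(x - k, 0) ** 3 - np.maximum(x - hi, 0) ** 3
        return num / max(hi - k, 1e-12)

    d_last = d(knots[-2])
    cols = [x] + [d(knots[i]) - d_last for i in range(len(knots) - 2)]
    return np.column_stack(cols)


def transition_genes(
    matrix: ExpressionMatrix,
    traj: Trajectory,
    leaf_state: int | None = None,
    genes: list | None = None,
    exclude_leaf: int | None = None,
    p_cut: float = DEFAULT_P_CUT,
    q_cut: float = DEFAULT_Q_CUT,
    spline_df: int = 3,
    min_cells: int = 30,
    min_expressing: int = 10,
) -> list:
    """Smooth pseudotime-dependent genes along the trajectory.

    Per gene, an NB GLM with a natural-spline basis of pseudotime (df=3)
    is tested against the intercept-only model (LRT chi-square, df=3).
    Significant genes (p < 0.005 and BH FDR < 0.05) carry a direction from
    the Spearman correlation of the fitted curve with pseudotime
    (|rho| < 0.2 -> "ambiguous").

    By default every trajectory cell enters the fit. To focus a genuinely
    branched trajectory on the root -> ``leaf_state`` path, pass the
    alternative fate as ``exclude_leaf``: its exclusive states (those not
    shared with the target path) are dropped. Automatic geometric branch
    exclusion is deliberately avoided — on linear data the embedding's
    noise forks would cut real path cells.
    """
    import statsmodels.api as sm

    mask = np.ones(traj.state.size, dtype=bool)
    if exclude_leaf is not None:
        on_path = set(traj.path_states(leaf_state)) if leaf_state is not None else set()
        exclusive = set(traj.path_states(exclude_leaf)) - on_path - {traj.root_state}
        mask &= ~np.isin(traj.state, list(exclusive))
    path_local = np.flatnonzero(mask)
    if path_local.size < min_cells:
        raise ValueError(f"only {path_local.size} cells on the path; need {min_cells}")
    order = path_local[np.argsort(traj.pseudotime[path_local], kind="stable")]
    cols = traj.cells[order]
    pt = traj.pseudotime[order]

    y_all = np.asarray(matrix.counts[:, cols].todense(), dtype=float)
    s = size_factors(matrix.total_counts()[cols])
    offset = np.log(s)
    symbols = matrix.gene_meta["symbol"].to_numpy()
    if genes is None:
        rows = np.arange(matrix.n_genes)
    else:
        rows = matrix.gene_index(genes)
    expressed = (y_all[rows] > 0).sum(axis=1) >= min_expressing
    rows = rows[expressed]

    # dispersion with pseudotime coarsely binned so real trends do not
    # inflate it
    bins = np.clip(
        np.digitize(pt, np.quantile(pt, [0.2, 0.4, 0.6, 0.8])), 0, 4
    )
    alpha = estimate_dispersion(y_all[rows], s, groups=bins)

    basis = natural_spline_basis(pt, df=spline_df)
    X_full = sm.add_constant(basis)
    X_null = np.ones((pt.size, 1))

    results = []
    stats = np.full((rows.size, 2), np.nan)  # lrt, p
    fitted_store = {}
    for gi, row in enumerate(rows):
        y = y_all[row]
        fam = sm.families.NegativeBinomial(alpha=max(alpha[gi], 1e-8))
        try:
            full = sm.GLM(y, X_full, family=fam, offset=offset).fit(maxiter=100)
            null = sm.GLM(y, X_null, family=fam, offset=offset).fit(maxiter=100)
        except Exception:  # non-convergence on degenerate genes
            continue
        lrt = max(2.0 * (full.llf - null.llf), 0.0)
        stats[gi] = (lrt, chi2.sf(lrt, spline_df))
        fitted_store[gi] = full.fittedvalues / s  # depth-corrected curve
    q = bh_adjust(stats[:, 1])
    for gi, row in enumerate(rows):
        lrt, p = stats[gi]
        if not np.isfinite(p) or not (p < p_cut and q[gi] < q_cut):
            continue
        fitted = fitted_store[gi]
        rho = spearmanr(fitted, pt).statistic
        if not np.isfinite(rho):
            rho = 0.0
        direction = (
            "ambiguous" if abs(rho) < AMBIGUOUS_RHO else ("up" if rho > 0 else "down")
        )
        results.append(
            TransitionGeneResult(
                gene=str(symbols[row]),
                lrt=float(lrt),
                pvalue=float(p),
                qvalue=float(q[gi]),
                direction=direction,
                rho=float(rho),
                fitted=fitted,
            )
        )
    results.sort(key=lambda r: r.pvalue)
    return results
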