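"""Expression-based CNV inference and malignant-cell calling.

Large-scale copy-number changes shift the average expression of long runs
of chromosomally adjacent genes. Per chromosome, genes are ordered by
position and averaged in sliding windows (200 genes, step 50) after
centering each gene on its mean over a reference (nonmalignant) cell set,
so copy-neutral cells score near zero. A window whose per-cell scores are
better described by a two-component Gaussian mixture than by one component
(likelihood-ratio chi-square, df=2, pooled variance, BH-corrected across
windows) is a CNV candidate region; cells assigned to the component away
from the reference mean in one or more significant regions are flagged as
putative malignant cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .containers import ExpressionMatrix

DEFAULT_WINDOW = 200
DEFAULT_STEP = 50
DEFAULT_ALPHA = 0.05
_VAR_FLOOR = 1e-4


@dataclass
class CNVWindow:
    window_id: int
    chromosome: str
    genes: list
    scores: np.ndarray  # per-cell mean centered log expression
    short: bool = False
    means: tuple | None = None  # 2-component means
    variance: float | None = None  # pooled
    weight: float | None = None  # weight of component 0
    lrt: float | None = None
    pvalue: float | None = None
    padj: float | None = None
    degenerate: bool = False


@dataclass
class CNVCallSet:
    significant: list  # CNVWindow
    malignant: np.ndarray  # bool per cell
    assignments: pd.DataFrame  # cells x significant windows, 1 = aberrant
    reference_cells: np.ndarray
    excluded_windows: list = field(default_factory=list)


def window_scores(
    matrix: ExpressionMatrix,
    reference_cells: np.ndarray,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list:
    """Sliding-window mean of reference-centered log expression.

    Chromosomes shorter than ``window`` yield a single whole-chromosome
    window flagged ``short``. The mitochondrial contig is skipped.
    """
    if matrix.log_layer is None:
        raise ValueError("log layer missing; call normalize_log first")
    reference_cells = np.asarray(reference_cells)
    if reference_cells.dtype == bool:
        reference_cells = np.flatnonzero(reference_cells)
    if reference_cells.size == 0:
        raise ValueError("empty reference cell set")
    centered = matrix.log_layer - matrix.log_layer[:, reference_cells].mean(
        axis=1, keepdims=True
    )
    # remove per-cell global shifts (library depth / detection efficiency)
    # so window scores reflect regional deviations only
    autosomal = (matrix.gene_meta["chromosome"] != "MT").to_numpy()
    centered = centered - centered[autosomal].mean(axis=0, keepdims=True)
    windows = []
    wid = 0
    gm = matrix.gene_meta
    for chrom in pd.unique(gm["chromosome"]):
        if chrom == "MT":
            continue
        rows = np.flatnonzero((gm["chromosome"] == chrom).to_numpy())
        rows = rows[np.argsort(gm["position"].to_numpy()[rows], kind="stable")]
        if rows.size < window:
            starts, short = [0], True
            size = rows.size
        else:
            starts = list(range(0, rows.size - window + 1, step))
            short, size = False, window
        for s in starts:
            member = rows[s : s + size]
            windows.append(
                CNVWindow(
                    window_id=wid,
                    chromosome=str(chrom),
                    genes=list(gm["symbol"].to_numpy()[member]),
                    scores=centered[member].mean(axis=0),
                    short=short,
                )
            )
            wid += 1
    return windows


def _fit_gmm2(x: np.ndarray, seed: int = 0) -> tuple:
    """Two-component tied-variance Gaussian mixture; returns (m0, m1, var, w0, ll)."""
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=2,
        covariance_type="tied",
        n_init=10,
        tol=1e-6,
        max_iter=500,
        reg_covar=_VAR_FLOOR,
        random_state=seed,
        init_params="kmeans",
    ).fit(x[:, None])
    ll = gm.score(x[:, None]) * x.size
    m = gm.means_.ravel()
    var = float(gm.covariances_.ravel()[0])
    return float(m[0]), float(m[1]), var, float(gm.weights_[0]), float(ll)


def fit_mixture_test(window: CNVWindow, seed: int = 0) -> CNVWindow:
    """LRT of 2-component vs 1-component Gaussian fit on the window scores."""
    x = np.asarray(window.scores, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 cells for the mixture test")
    var1 = max(x.var(), _VAR_FLOOR)
    ll1 = norm.logpdf(x, x.mean(), np.sqrt(var1)).sum()
    m0, m1, var2, w0, ll2 = _fit_gmm2(x, seed=seed)
    window.degenerate = var2 <= _VAR_FLOOR * 1.01
    window.means = (m0, m1)
    window.variance = var2
    window.weight = w0
    window.lrt = max(2.0 * (ll2 - ll1), 0.0)
    window.pvalue = float(chi2.sf(window.lrt, 2))
    return window


def run_window_tests(windows: list, seed: int = 0) -> list:
    """Fit every window and fill BH-adjusted p-values across windows."""
    from .nbstats import bh_adjust

    for w in windows:
        fit_mixture_test(w, seed=seed)
    padj = bh_adjust(np.array([w.pvalue for w in windows]))
    for w, q in zip(windows, padj):
        w.padj = float(q)
    return windows


def call_malignant(
    windows: list,
    reference_cells: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    max_reference_aberrant: float = 0.4,
) -> CNVCallSet:
    """Flag cells assigned to the aberrant component of >= 1 significant region.

    In each significant window the component whose mean is closer to the
    reference-cell mean score is neutral; the other is aberrant. Windows in
    which the reference cells split nearly evenly between components carry
    no signal about which side is neutral and are excluded.
    """
    reference_cells = np.asarray(reference_cells)
    if reference_cells.dtype == bool:
        reference_cells = np.flatnonzero(reference_cells)
    if reference_cells.size == 0:
        raise ValueError("empty reference cell set")
    n_cells = windows[0].scores.size if windows else 0
    sig = [w for w in windows if w.padj is not None and w.padj < alpha]
    kept, excluded, columns = [], [], {}
    for w in sig:
        ref_mean = w.scores[reference_cells].mean()
        m = np.array(w.means)
        sd = np.sqrt(max(w.variance, _VAR_FLOOR))
        weights = np.array([w.weight, 1.0 - w.weight])
        # posterior component assignment per cell
        logp = (
            np.log(np.maximum(weights, 1e-12))[None, :]
            + norm.logpdf(w.scores[:, None], m[None, :], sd)
        )
        comp = np.argmax(logp, axis=1)
        neutral = int(np.argmin(np.abs(m - ref_mean)))
        aberrant_mask = comp != neutral
        ref_aberrant = aberrant_mask[reference_cells].mean()
        if min(ref_aberrant, 1 - ref_aberrant) > max_reference_aberrant:
            excluded.append(w)
            continue
        kept.append(w)
        columns[w.window_id] = aberrant_mask.astype(int)
    assignments = pd.DataFrame(columns, index=pd.RangeIndex(n_cells))
    malignant = (
        assignments.to_numpy().any(axis=1)
        if len(columns)
        else np.zeros(n_cells, dtype=bool)
    )
    return CNVCallSet(
        significant=kept,
        malignant=np.asarray(malignant, dtype=bool),
        assignments=assignments,
        reference_cells=reference_cells,
        excluded_windows=excluded,
    )


def infer_cnv(
    matrix: ExpressionMatrix,
    reference_cells: np.ndarray,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> CNVCallSet:
    """Window scores -> mixture tests -> malignancy calls, end to end."""
    windows = window_scores(matrix, reference_cells, window=window, step=step)
    run_window_tests(windows, seed=seed)
    return call_malignant(windows, reference_cells, alpha=alpha)
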