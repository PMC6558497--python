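"""Synthetic scRNA-seq data with planted ground truth.

Generates UMI count matrices that emulate a paired tumor/normal single-cell
experiment: negative-binomial counts with cell-type-specific marker
elevation, a monocyte-to-macrophage style differentiation trajectory with
monotone transition genes (one or two fate branches), dosage-shifted CNV
regions in a malignant subpopulation of tumor tissue, tissue-biased
composition, planted ligand-receptor channels between an epithelial-like
and a myeloid-like population, a sparse TF->target co-expression network,
and a block of planted low-quality cells for QC testing.

The generative model for the expected count of gene g in cell c is

    mu_gc = L_c * w_gc / sum_g w_gc

where L_c is the cell's library size and the relative rate w_gc is a
log-normal gene baseline multiplied by 2^boost factors for markers,
transition genes (scaled by pseudotime), CNV dosage (malignant cells only)
and regulator activity. Counts are drawn NB(mu, alpha) with variance
mu + alpha * mu^2, alpha shared across genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ExpressionMatrix

N_MITO_GENES = 13
BRANCH_POINT = 0.5


class SpecValidationError(ValueError):
    """Inconsistent synthetic specification."""


@dataclass
class TrajectorySpec:
    """Differentiation trajectory plan.

    ``types`` orders the participating cell types: root first, then one
    fate per branch. Transition genes change monotonically (2^(effect_log2 *
    pseudotime)) along the root -> first-fate path.
    """

    types: tuple = ("CD14+ monocyte", "M2 macrophage")
    n_transition_genes_up: int = 50
    n_transition_genes_down: int = 50
    effect_log2: float = 2.0
    n_branches: int = 1

    def __post_init__(self) -> None:
        if self.n_branches not in (1, 2):
            raise SpecValidationError("n_branches must be 1 or 2")
        if len(self.types) != 1 + self.n_branches:
            raise SpecValidationError(
                "trajectory.types must list the root type then one fate per branch"
            )


@dataclass
class CNVRegionSpec:
    chromosome: str
    start: int  # gene index within the chromosome
    length: int  # genes
    dosage: float  # copy-dosage multiplier, e.g. 0.5, 1.5, 2.0

    def __post_init__(self) -> None:
        if self.dosage <= 0:
            raise SpecValidationError("dosage must be positive")
        if self.length < 1 or self.start < 0:
            raise SpecValidationError("bad CNV region extent")


@dataclass
class CNVSpec:
    regions: list = field(default_factory=list)
    malignant_fraction: float = 0.0
    malignant_type: str = "epithelial"

    def __post_init__(self) -> None:
        self.regions = [
            r if isinstance(r, CNVRegionSpec) else CNVRegionSpec(*r)
            for r in self.regions
        ]
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise SpecValidationError("malignant_fraction outside [0,1]")


@dataclass
class LRChannel:
    ligand: str
    receptor: str
    source_type: str
    target_type: str


@dataclass
class GRNSpec:
    n_tfs: int = 10
    n_targets: int = 50
    edges_per_target: int = 3
    effect: float = 1.0  # log2 response of a target to one s.d. of TF activity


@dataclass
class LowQSpec:
    count: int = 0
    gene_detection: int = 100  # must stay below the QC min-genes threshold
    mito_fraction: float = 0.6  # must exceed the QC mito threshold

    def __post_init__(self) -> None:
        if self.count and self.gene_detection >= 200:
            raise SpecValidationError("low-quality cells must detect < 200 genes")
        if self.count and self.mito_fraction <= 0.4:
            raise SpecValidationError("low-quality mito fraction must exceed 0.4")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset.

    ``n_cells_per_type`` maps cell type -> {tissue: count}. Defaults emulate
    a paired tumor/normal lung specimen: an epithelial compartment with a
    malignant tumor subpopulation, a myeloid differentiation trajectory
    rooted in normal-tissue monocytes with an M2-like fate enriched in
    tumor, and a lymphoid background population.
    """

    n_cells_per_type: dict = field(
        default_factory=lambda: {
            "epithelial": {"tumor": 200, "normal": 100},
            "CD14+ monocyte": {"tumor": 100, "normal": 200},
            "M2 macrophage": {"tumor": 200, "normal": 50},
            "T cell": {"tumor": 150, "normal": 150},
        }
    )
    n_genes: int = 2000
    marker_genes_per_type: int = 10
    marker_log2_boost: float = 2.0
    nb_dispersion: float = 0.3
    library_size_mean: int = 3000
    library_size_cv: float = 0.3
    trajectory: TrajectorySpec | None = field(default_factory=TrajectorySpec)
    cnv: CNVSpec = field(
        default_factory=lambda: CNVSpec(
            regions=[CNVRegionSpec("chr7", 0, 200, 2.0)], malignant_fraction=0.3
        )
    )
    lr_channels: list = field(
        default_factory=lambda: [
            LRChannel("SFTPA1", "TLR2", "epithelial", "CD14+ monocyte"),
            LRChannel("ICAM1", "ITGAM", "epithelial", "M2 macrophage"),
            LRChannel("CYR61", "ITGAM", "epithelial", "M2 macrophage"),
            LRChannel("CTGF", "ITGAM", "epithelial", "M2 macrophage"),
        ]
    )
    grn: GRNSpec | None = field(default_factory=GRNSpec)
    lowq_cells: LowQSpec = field(default_factory=lambda: LowQSpec(count=30))
    baseline_log_sd: float = 1.0
    mito_share: float = 0.05
    n_chromosomes: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.trajectory, dict):
            self.trajectory = TrajectorySpec(**self.trajectory)
        if isinstance(self.cnv, dict):
            self.cnv = CNVSpec(**self.cnv)
        if isinstance(self.grn, dict):
            self.grn = GRNSpec(**self.grn)
        if isinstance(self.lowq_cells, dict):
            self.lowq_cells = LowQSpec(**self.lowq_cells)
        self.lr_channels = [
            c if isinstance(c, LRChannel) else LRChannel(*c) for c in self.lr_channels
        ]
        self.validate()

    @property
    def cell_types(self) -> list:
        return list(self.n_cells_per_type)

    def _n_special_genes(self) -> int:
        n = self.marker_genes_per_type * len(self.n_cells_per_type)
        if self.trajectory is not None:
            n += (
                self.trajectory.n_transition_genes_up
                + self.trajectory.n_transition_genes_down
            )
        if self.grn is not None:
            n += self.grn.n_tfs + self.grn.n_targets
        n += 2 * len(self.lr_channels)
        return n

    def validate(self) -> None:
        if self.nb_dispersion < 0:
            raise SpecValidationError("nb_dispersion must be >= 0")
        for t, per_tissue in self.n_cells_per_type.items():
            for tissue, n in per_tissue.items():
                if tissue not in ("tumor", "normal"):
                    raise SpecValidationError(f"unknown tissue {tissue!r}")
                if n < 0:
                    raise SpecValidationError("negative cell count")
        if self._n_special_genes() + N_MITO_GENES > self.n_genes:
            raise SpecValidationError(
                "n_genes too small for the requested markers/transition/"
                "network/ligand-receptor genes"
            )
        if self.trajectory is not None:
            for t in self.trajectory.types:
                if t not in self.n_cells_per_type:
                    raise SpecValidationError(
                        f"trajectory type {t!r} absent from n_cells_per_type"
                    )


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage."""

    cells: pd.DataFrame  # barcode, cell_type, tissue, patient, pseudotime, branch, malignant, lowq
    markers: dict  # type -> [gene symbols]
    transition_up: list
    transition_down: list
    cnv_regions: list  # dicts: chromosome, dosage, genes
    lr_channels: list  # LRChannel
    grn_edges: list  # (tf, target)
    tf_genes: list
    target_genes: list

    def to_json(self) -> str:
        payload = {
            "cells": self.cells.to_dict(orient="list"),
            "markers": self.markers,
            "transition_up": self.transition_up,
            "transition_down": self.transition_down,
            "cnv_regions": self.cnv_regions,
            "lr_channels": [asdict(c) for c in self.lr_channels],
            "grn_edges": [list(e) for e in self.grn_edges],
            "tf_genes": self.tf_genes,
            "target_genes": self.target_genes,
        }
        return json.dumps(payload, default=lambda o: None)


def _build_gene_table(spec: SyntheticSpec) -> pd.DataFrame:
    n_nuclear = spec.n_genes - N_MITO_GENES
    symbols = [f"G{i:05d}" for i in range(n_nuclear)]
    chrom_sizes = np.full(spec.n_chromosomes, n_nuclear // spec.n_chromosomes)
    chrom_sizes[: n_nuclear % spec.n_chromosomes] += 1
    chroms, positions = [], []
    for ci, size in enumerate(chrom_sizes):
        chroms.extend([f"chr{ci + 1}"] * size)
        positions.extend(range(size))
    symbols += [f"MT-G{i + 1}" for i in range(N_MITO_GENES)]
    chroms += ["MT"] * N_MITO_GENES
    positions += list(range(N_MITO_GENES))
    return pd.DataFrame(
        {
            "symbol": symbols,
            "chromosome": chroms,
            "position": positions,
            "mito": [c == "MT" for c in chroms],
        }
    )


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Sample a dataset and its ground truth; deterministic under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    gene_meta = _build_gene_table(spec)
    n_nuclear = spec.n_genes - N_MITO_GENES
    mito_idx = np.arange(n_nuclear, spec.n_genes)

    # CNV regions -> absolute gene indices (resolved first: role genes are
    # then scattered over the complement so sliding windows see cell-type
    # signal diluted, as in real chromosomes, rather than in planted blocks)
    chrom_index = {
        c: np.flatnonzero((gene_meta["chromosome"] == c).to_numpy())
        for c in gene_meta["chromosome"].unique()
    }
    cnv_gene_idx = []
    for region in spec.cnv.regions:
        if region.chromosome not in chrom_index:
            raise SpecValidationError(f"unknown chromosome {region.chromosome!r}")
        block = chrom_index[region.chromosome]
        if region.start + region.length > len(block):
            raise SpecValidationError("CNV region exceeds chromosome extent")
        cnv_gene_idx.append(block[region.start : region.start + region.length])

    # ---- gene role allocation: disjoint random draws from the non-CNV pool
    reserved = (
        np.concatenate(cnv_gene_idx) if cnv_gene_idx else np.array([], dtype=int)
    )
    pool = np.setdiff1d(np.arange(n_nuclear), reserved)
    pool = rng.permutation(pool)
    if pool.size < spec._n_special_genes():
        raise SpecValidationError(
            "n_genes too small for the requested roles outside the CNV regions"
        )
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        block = np.sort(pool[cursor : cursor + k])
        cursor += k
        return block

    types = spec.cell_types
    marker_idx = {t: take(spec.marker_genes_per_type) for t in types}
    traj = spec.trajectory
    up_idx = take(traj.n_transition_genes_up) if traj else np.array([], int)
    down_idx = take(traj.n_transition_genes_down) if traj else np.array([], int)
    tf_idx = take(spec.grn.n_tfs) if spec.grn else np.array([], int)
    target_idx = take(spec.grn.n_targets) if spec.grn else np.array([], int)
    lr_names = list(
        dict.fromkeys(
            [c.ligand for c in spec.lr_channels]
            + [c.receptor for c in spec.lr_channels]
        )
    )
    lr_idx = take(len(lr_names))
    lr_gene = dict(zip(lr_names, lr_idx))
    for name, gi in lr_gene.items():
        gene_meta.loc[gi, "symbol"] = name
    symbols = gene_meta["symbol"].to_numpy()

    cnv_records = []
    for idx, region in zip(cnv_gene_idx, spec.cnv.regions):
        cnv_records.append(
            {
                "chromosome": region.chromosome,
                "start": int(region.start),
                "length": int(region.length),
                "dosage": float(region.dosage),
                "genes": [symbols[i] for i in idx],
            }
        )

    # ---- cell table
    rows = []
    for t in types:
        for tissue, n in spec.n_cells_per_type[t].items():
            rows.extend({"cell_type": t, "tissue": tissue} for _ in range(n))
    cells = pd.DataFrame(rows)
    n_good = len(cells)

    # trajectory: pool participating cells, draw pseudotime, reassign types
    pseudotime = np.full(n_good, np.nan)
    branch = np.array(["none"] * n_good, dtype=object)
    if traj is not None:
        participating = cells["cell_type"].isin(traj.types).to_numpy()
        part = np.flatnonzero(participating)
        pt = rng.uniform(0, 1, size=part.size)
        is_normal = (cells["tissue"].to_numpy()[part] == "normal")
        # normal-tissue cells concentrate early so the root is normal-enriched
        early = rng.random(part.size) < 0.8
        pt[is_normal & early] *= 0.3
        n_root = sum(spec.n_cells_per_type[traj.types[0]].values())
        order = np.argsort(pt)
        root_cells = part[order[:n_root]]
        fate_cells = part[order[n_root:]]
        ct = cells["cell_type"].to_numpy(dtype=object)
        ct[root_cells] = traj.types[0]
        if traj.n_branches == 1:
            ct[fate_cells] = traj.types[1]
            br = np.array([traj.types[1]] * fate_cells.size, dtype=object)
        else:
            n_fate1 = sum(spec.n_cells_per_type[traj.types[1]].values())
            fate_labels = np.array(
                [traj.types[1]] * n_fate1
                + [traj.types[2]] * (fate_cells.size - n_fate1),
                dtype=object,
            )
            rng.shuffle(fate_labels)
            ct[fate_cells] = fate_labels
            br = fate_labels
        cells["cell_type"] = ct
        pseudotime[part] = pt
        branch[root_cells] = "root"
        branch[fate_cells] = br
    cells["pseudotime"] = pseudotime
    cells["branch"] = branch

    # malignant subpopulation: tumor-tissue cells of the designated type
    malignant = np.zeros(n_good, dtype=bool)
    if spec.cnv.malignant_fraction > 0 and spec.cnv.regions:
        pool = np.flatnonzero(
            (cells["cell_type"] == spec.cnv.malignant_type).to_numpy()
            & (cells["tissue"] == "tumor").to_numpy()
        )
        k = int(round(spec.cnv.malignant_fraction * pool.size))
        malignant[rng.choice(pool, size=k, replace=False)] = True
    cells["malignant"] = malignant
    cells["lowq"] = False

    # planted low-quality cells
    if spec.lowq_cells.count:
        lq = pd.DataFrame(
            {
                "cell_type": "low_quality",
                "tissue": rng.choice(["tumor", "normal"], size=spec.lowq_cells.count),
                "pseudotime": np.nan,
                "branch": "none",
                "malignant": False,
                "lowq": True,
            }
        )
        cells = pd.concat([cells, lq], ignore_index=True)
    n_cells = len(cells)
    cells["patient"] = "P1"
    cells["barcode"] = [f"CELL{i:06d}" for i in range(n_cells)]

    # ---- relative rates in log2 space
    base = rng.normal(0.0, spec.baseline_log_sd, size=spec.n_genes) / np.log(2)
    # role genes (cell-type markers, the transition program, regulators and
    # their targets) model transcripts that are well expressed by
    # construction — markers and transition genes come out of differential
    # screens, and a near-silent TF transcript carries no activity readout.
    # Fold their baselines to the upper half of the distribution.
    role_blocks = [up_idx, down_idx, tf_idx, target_idx] + list(marker_idx.values())
    for block in role_blocks:
        base[block] = np.abs(base[block])
    log2w = np.tile(base[:, None], (1, n_cells))

    ctype = cells["cell_type"].to_numpy()
    for t in types:
        cols = np.flatnonzero(ctype == t)
        log2w[np.ix_(marker_idx[t], cols)] += spec.marker_log2_boost

    if traj is not None:
        on_traj = np.flatnonzero(~np.isnan(cells["pseudotime"].to_numpy()))
        pt = cells["pseudotime"].to_numpy()[on_traj]
        # branch-2 cells on the alternate fate freeze at the branch point
        if traj.n_branches == 2:
            alt = cells["branch"].to_numpy()[on_traj] == traj.types[2]
            pt_eff = np.where(alt, np.minimum(pt, BRANCH_POINT), pt)
        else:
            pt_eff = pt
        log2w[np.ix_(up_idx, on_traj)] += traj.effect_log2 * pt_eff
        log2w[np.ix_(down_idx, on_traj)] -= traj.effect_log2 * pt_eff

    for idx, region in zip(cnv_gene_idx, spec.cnv.regions):
        cols = np.flatnonzero(malignant)
        if cols.size:
            log2w[np.ix_(idx, cols)] += np.log2(region.dosage)

    # a ligand/receptor gene is boosted in the union of its home types and
    # near-silent elsewhere
    home: dict[int, np.ndarray] = {}
    for ch in spec.lr_channels:
        for name, t in ((ch.ligand, ch.source_type), (ch.receptor, ch.target_type)):
            gi = lr_gene[name]
            mask = home.get(gi, np.zeros(n_cells, dtype=bool))
            home[gi] = mask | (ctype == t)
    # outside its home types an LR gene is effectively silent: the planted
    # channel contract is type-exclusive expression under the >=1-cell rule
    for gi, mask in home.items():
        log2w[gi, mask] += spec.marker_log2_boost + 1
        log2w[gi, ~mask] -= 20

    grn_edges: list = []
    if spec.grn is not None and spec.grn.n_tfs:
        activity = rng.normal(0.0, 1.0, size=(spec.grn.n_tfs, n_cells))
        log2w[tf_idx] += spec.grn.effect * activity
        for j, tg in enumerate(target_idx):
            parents = rng.choice(
                spec.grn.n_tfs, size=min(spec.grn.edges_per_target, spec.grn.n_tfs),
                replace=False,
            )
            log2w[tg] += (
                spec.grn.effect * activity[parents].mean(axis=0) * np.sqrt(len(parents))
            )
            grn_edges.extend((symbols[tf_idx[p]], symbols[tg]) for p in parents)

    w = np.exp2(log2w)

    # ---- mitochondrial share and library sizes
    mshare = np.where(
        cells["lowq"].to_numpy(), spec.lowq_cells.mito_fraction, spec.mito_share
    )
    conc = 200.0
    mshare = rng.beta(conc * mshare, conc * (1 - mshare))
    nonmito = np.ones(spec.n_genes, dtype=bool)
    nonmito[mito_idx] = False
    w_n = w[nonmito]
    w_m = w[~nonmito]
    w_n = w_n / w_n.sum(axis=0, keepdims=True) * (1 - mshare)
    w_m = w_m / w_m.sum(axis=0, keepdims=True) * mshare
    probs = np.empty_like(w)
    probs[nonmito] = w_n
    probs[~nonmito] = w_m

    sigma = np.sqrt(np.log1p(spec.library_size_cv**2))
    lib = rng.lognormal(np.log(spec.library_size_mean) - sigma**2 / 2, sigma, n_cells)
    lib = np.where(cells["lowq"].to_numpy(), float(spec.lowq_cells.gene_detection), lib)

    mu = probs * lib[None, :]
    if spec.nb_dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / spec.nb_dispersion
        lam = rng.gamma(shape, mu * spec.nb_dispersion)
        counts = rng.poisson(lam)

    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_meta=gene_meta,
        cell_meta=cells[["barcode", "patient", "tissue"]].copy(),
    )
    truth = GroundTruth(
        cells=cells[
            ["barcode", "cell_type", "tissue", "patient", "pseudotime", "branch",
             "malignant", "lowq"]
        ].copy(),
        markers={t: [symbols[i] for i in marker_idx[t]] for t in types},
        transition_up=[symbols[i] for i in up_idx],
        transition_down=[symbols[i] for i in down_idx],
        cnv_regions=cnv_records,
        lr_channels=list(spec.lr_channels),
        grn_edges=grn_edges,
        tf_genes=[symbols[i] for i in tf_idx],
        target_genes=[symbols[i] for i in target_idx],
    )
    return matrix, truth


def write_dataset(matrix: ExpressionMatrix, truth: GroundTruth, outdir: str | Path) -> None:
    """Write triplet files, cell metadata and the ground-truth JSON."""
    from .io import write_matrix

    outdir = Path(outdir)
    write_matrix(matrix, outdir)
    (outdir / "ground_truth.json").write_text(truth.to_json())
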