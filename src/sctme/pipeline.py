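"""End-to-end orchestration with a single config and a run manifest.

Stages run in a fixed order — qc, cluster, annotate, cnv, trajectory,
enrich, crosstalk, grn, subsets — each gated by a toggle and consuming the
outputs of its predecessors. A stage failure halts the run; the manifest
records completed stages, parameter echo, the seed, and a content hash for
every output file so deterministic stages can be re-verified.

Inputs come either from a triplet directory (``input_dir``) plus marker /
ligand-receptor / gene-set side files, or from the synthetic generator
(``synthetic=True``), in which case marker tables, the LR database and the
regulator lists are derived from the planted ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = [
    "qc", "cluster", "annotate", "cnv", "trajectory", "enrich", "crosstalk",
    "grn", "subsets",
]
_DEPENDS = {
    "cluster": ["qc"],
    "annotate": ["cluster"],
    "cnv": ["cluster"],
    "trajectory": ["annotate"],
    "enrich": ["trajectory"],
    "crosstalk": ["annotate"],
    "grn": ["trajectory"],
    "subsets": ["annotate"],
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the published analysis values."""

    input_dir: str | None = None
    out_dir: str = "sctme_run"
    synthetic: bool = True
    stages: list = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    # qc
    min_genes: int = 200
    max_mito: float = 0.40
    min_cells: int = 5
    # cluster
    n_pcs: int = 30
    resolution: float = 1.0
    embedding: str = "pca"
    # annotate
    score_alpha: float = 0.05
    positive_only: bool = False
    markers_file: str | None = None
    # cnv
    cnv_window: int = 200
    cnv_step: int = 50
    cnv_alpha: float = 0.05
    # trajectory
    root_type: str = "CD14+ monocyte"
    root_tissue: str = "normal"
    fate_type: str = "M2 macrophage"
    p_cut: float = 0.005
    q_cut: float = 0.05
    # enrichment
    enrich_alpha: float = 0.05
    gmt_file: str | None = None
    # crosstalk
    lr_file: str | None = None
    receptors_file: str | None = None
    # grn / subsets
    n_trees: int = 200
    regulators_file: str | None = None
    subset_ligands: list = field(
        default_factory=lambda: ["SFTPA1", "ICAM1", "CTGF", "CYR61"]
    )
    subset_q_cut: float = 0.01
    subset_lfc_cut: float = 1.0

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            for dep in _DEPENDS.get(stage, []):
                if dep not in self.stages:
                    raise ConfigError(f"stage {stage!r} requires {dep!r}")
        if not self.synthetic and self.input_dir is None:
            raise ConfigError("input_dir required when synthetic=False")
        if not (0 <= self.max_mito <= 1):
            raise ConfigError("max_mito outside [0,1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    from . import annotate as ann
    from . import cnv as cnvmod
    from . import crosstalk as ct
    from . import grn as grnmod
    from . import preprocess as pp
    from . import qc as qcmod
    from . import subsets as subs
    from . import synthetic as synth
    from . import trajectory as traj
    from .io import read_matrix, write_qc_report

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages_completed": [],
        "summaries": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _hash_file(path)}

    def finish(status: str) -> dict:
        manifest["status"] = status
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    truth = None
    if config.synthetic:
        spec = synth.SyntheticSpec(seed=config.seed)
        matrix, truth = synth.generate_dataset(spec)
    else:
        matrix = read_matrix(config.input_dir)

    try:
        clustering = None
        scores = None
        trajectory_obj = None
        transition = None
        interactions = None

        if "qc" in config.stages:
            matrix, report = qcmod.run_qc(
                matrix, config.min_genes, config.max_mito, config.min_cells
            )
            write_qc_report(report, out / "qc_report.json")
            record("qc_report", out / "qc_report.json")
            manifest["summaries"]["qc"] = report.to_dict()
            manifest["stages_completed"].append("qc")

        if "cluster" in config.stages:
            pp.normalize_log(matrix)
            residuals = pp.regress_out(matrix)
            hvg = pp.select_variable_genes(matrix)
            clustering = pp.pca_embed_cluster(
                matrix,
                residuals=residuals,
                variable_genes=hvg,
                n_pcs=config.n_pcs,
                resolution=config.resolution,
                embedding=config.embedding,
                seed=config.seed,
            )
            df = pd.DataFrame(
                {
                    "barcode": matrix.cell_meta["barcode"],
                    "cluster": clustering.labels,
                    "emb1": clustering.embedding[:, 0],
                    "emb2": clustering.embedding[:, 1],
                }
            )
            df.to_csv(out / "clusters.tsv", sep="\t", index=False)
            record("clusters", out / "clusters.tsv")
            manifest["summaries"]["cluster"] = {
                "n_clusters": clustering.n_clusters,
                "n_variable_genes": len(hvg),
            }
            manifest["stages_completed"].append("cluster")

        if "annotate" in config.stages:
            if config.markers_file:
                from .io import load_marker_table

                marker_sets = load_marker_table(config.markers_file)
            elif truth is not None:
                marker_sets = truth.markers
            else:
                marker_sets = ann.BUILTIN_MARKERS
            scores = ann.cluster_type_scores(
                matrix, clustering, marker_sets,
                alpha=config.score_alpha, positive_only=config.positive_only,
            )
            scores.scores.to_csv(out / "type_scores.tsv", sep="\t")
            scores.assignment.to_csv(out / "cluster_types.tsv", sep="\t")
            record("type_scores", out / "type_scores.tsv")
            record("cluster_types", out / "cluster_types.tsv")
            manifest["summaries"]["annotate"] = {
                "assignment": {str(k): v for k, v in scores.assignment.items()}
            }
            manifest["stages_completed"].append("annotate")

        cell_types = None
        if scores is not None:
            cell_types = scores.assignment.reindex(clustering.labels).to_numpy()

        if "cnv" in config.stages:
            reference = (matrix.cell_meta["tissue"] == "normal").to_numpy()
            callset = cnvmod.infer_cnv(
                matrix, reference,
                window=config.cnv_window, step=config.cnv_step,
                alpha=config.cnv_alpha, seed=config.seed,
            )
            pd.DataFrame(
                {
                    "barcode": matrix.cell_meta["barcode"],
                    "malignant": callset.malignant,
                }
            ).to_csv(out / "malignancy.tsv", sep="\t", index=False)
            record("malignancy", out / "malignancy.tsv")
            manifest["summaries"]["cnv"] = {
                "n_significant_regions": len(callset.significant),
                "n_malignant": int(callset.malignant.sum()),
            }
            manifest["stages_completed"].append("cnv")

        if "trajectory" in config.stages:
            myeloid = np.isin(cell_types, [config.root_type, config.fate_type, "CD1c+ DC"])
            cells = np.flatnonzero(myeloid)
            genes = traj.ordering_genes(matrix, clustering.labels, cells)
            root_mask = (cell_types == config.root_type) & (
                matrix.cell_meta["tissue"].to_numpy() == config.root_tissue
            )
            trajectory_obj = traj.learn_trajectory(
                matrix, genes, cells, root_mask, seed=config.seed
            )
            fates = traj.assign_fates(trajectory_obj, cell_types, config.fate_type)
            transition = traj.transition_genes(
                matrix, trajectory_obj, fates["AT1"],
                p_cut=config.p_cut, q_cut=config.q_cut,
            )
            pd.DataFrame(
                {
                    "barcode": matrix.cell_meta["barcode"].to_numpy()[trajectory_obj.cells],
                    "pseudotime": trajectory_obj.pseudotime,
                    "state": trajectory_obj.state,
                }
            ).to_csv(out / "trajectory.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    {"gene": r.gene, "pvalue": r.pvalue, "qvalue": r.qvalue,
                     "direction": r.direction, "rho": r.rho}
                    for r in transition
                ]
            ).to_csv(out / "transition_genes.tsv", sep="\t", index=False)
            record("trajectory", out / "trajectory.tsv")
            record("transition_genes", out / "transition_genes.tsv")
            manifest["summaries"]["trajectory"] = {
                "n_cells": int(cells.size),
                "n_states": int(np.unique(trajectory_obj.state).size),
                "n_transition_genes": len(transition),
                "fates": {k: (int(v) if v is not None else None) for k, v in fates.items()},
            }
            manifest["stages_completed"].append("trajectory")

        if "enrich" in config.stages and config.gmt_file:
            from .genesets import hypergeom_enrich, load_gmt

            collection = load_gmt(config.gmt_file)
            universe = list(matrix.gene_meta["symbol"])
            up = [r.gene for r in transition if r.direction == "up"]
            res = hypergeom_enrich(up, collection, universe, alpha=config.enrich_alpha)
            res.to_csv(out / "enrichment_up.tsv", sep="\t", index=False)
            record("enrichment_up", out / "enrichment_up.tsv")
            manifest["summaries"]["enrich"] = {
                "n_significant": int(res["significant"].sum()) if len(res) else 0
            }
            manifest["stages_completed"].append("enrich")
        elif "enrich" in config.stages:
            manifest["summaries"]["enrich"] = {"skipped": "no gmt_file provided"}

        if "crosstalk" in config.stages:
            if config.lr_file:
                db = ct.load_lr_pairs(config.lr_file)
            elif truth is not None:
                db = ct.LRDatabase(
                    pd.DataFrame(
                        [{"ligand": c.ligand, "receptor": c.receptor} for c in truth.lr_channels]
                    )
                )
            else:
                raise ConfigError("crosstalk stage needs lr_file")
            interactions = ct.infer_interactions(matrix, cell_types, db)
            interactions.to_csv(out / "interactions.tsv", sep="\t", index=False)
            record("interactions", out / "interactions.tsv")
            manifest["summaries"]["crosstalk"] = {"n_interactions": len(interactions)}
            manifest["stages_completed"].append("crosstalk")

        if "grn" in config.stages:
            if transition:
                target_genes = [r.gene for r in transition]
            elif truth is not None:
                target_genes = truth.target_genes
            else:
                raise ConfigError("grn stage needs trajectory output or ground truth")
            if config.regulators_file:
                regulators = [
                    ln.strip()
                    for ln in Path(config.regulators_file).read_text().splitlines()
                    if ln.strip()
                ]
            elif truth is not None:
                regulators = truth.tf_genes
                target_genes = truth.target_genes
            else:
                raise ConfigError("grn stage needs regulators_file")
            network = grnmod.infer_grn(
                matrix, target_genes, regulators,
                n_trees=config.n_trees, seed=config.seed,
            )
            network.edges.to_csv(out / "grn_edges.tsv", sep="\t", index=False)
            record("grn_edges", out / "grn_edges.tsv")
            manifest["summaries"]["grn"] = {
                "n_edges": len(network.edges),
                "hub": network.hub if len(network.edges) else None,
            }
            manifest["stages_completed"].append("grn")

        if "subsets" in config.stages:
            epi = [
                cl for cl, t in scores.assignment.items() if t == "epithelial"
            ] or list(scores.assignment.index)
            comparison = subs.split_subsets(
                matrix, clustering.labels, epi, config.subset_ligands
            )
            if (comparison.subset == 1).sum() >= 10 and (comparison.subset == 2).sum() >= 10:
                subs.subset_de(
                    matrix, comparison,
                    lfc_cut=config.subset_lfc_cut, q_cut=config.subset_q_cut,
                )
            comparison.tissue_fractions.to_csv(out / "subset_tissue.tsv", sep="\t")
            record("subset_tissue", out / "subset_tissue.tsv")
            manifest["summaries"]["subsets"] = {
                "qualifying_clusters": [int(c) for c in comparison.qualifying_clusters],
                "n_subset1": int((comparison.subset == 1).sum()),
                "n_subset2": int((comparison.subset == 2).sum()),
                "n_up": len(comparison.up_in_subset1),
                "n_down": len(comparison.down_in_subset1),
            }
            manifest["stages_completed"].append("subsets")
    except Exception as exc:  # halt, record what completed
        logger.exception("pipeline stage failed")
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        return finish("failed")
    return finish("ok")
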