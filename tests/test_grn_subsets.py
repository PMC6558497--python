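"""Tree-ensemble regulatory networks; epithelial subset split and DE."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from sctme import infer_grn, normalize_log, split_subsets, subset_de
from sctme import SyntheticSpec, generate_dataset

from conftest import prepared, toy_matrix


def grn_spec(seed, effect=1.0):
    return SyntheticSpec(
        n_cells_per_type={"CD14+ monocyte": {"tumor": 150, "normal": 150}},
        seed=seed,
        lowq_cells={"count": 0},
        lr_channels=[],
        cnv={"regions": [], "malignant_fraction": 0.0},
        trajectory=None,
        grn={"n_tfs": 10, "n_targets": 50, "edges_per_target": 3, "effect": effect},
    )


class TestGRN:
    def test_importances_normalized_and_no_self_edges(self):
        m, truth = prepared(grn_spec(seed=0))
        regs = truth.tf_genes + [truth.target_genes[0]]
        net = infer_grn(m, truth.target_genes[:5], regs, n_trees=50, seed=0)
        assert (net.edges["importance"] >= 0).all()
        per_target = net.edges.groupby("target")["importance"].sum()
        assert np.allclose(per_target, 1.0, atol=1e-6)
        assert not (net.edges["regulator"] == net.edges["target"]).any()

    def test_planted_edges_recovered(self):
        m, truth = prepared(grn_spec(seed=1))
        net = infer_grn(m, truth.target_genes, truth.tf_genes, n_trees=200, seed=1)
        true_edges = set(map(tuple, truth.grn_edges))
        y = [
            int((r.regulator, r.target) in true_edges)
            for r in net.edges.itertuples()
        ]
        assert roc_auc_score(y, net.edges["importance"]) >= 0.8

    def test_null_network_has_no_dominant_hub(self):
        m, truth = prepared(grn_spec(seed=2, effect=0.0))
        net = infer_grn(m, truth.target_genes, truth.tf_genes, n_trees=100, seed=2)
        hs = net.hub_scores
        assert hs.max() / hs.mean() < 3.0

    def test_duplicated_regulator_splits_importance(self):
        m, truth = prepared(grn_spec(seed=3))
        tf = truth.tf_genes[0]
        row = m.gene_index([tf])[0]
        # append an exact copy of the regulator's expression as a new gene
        counts = sp.vstack([m.counts, m.counts[row]]).tocsr()
        gene_meta = pd.concat(
            [m.gene_meta, pd.DataFrame([{
                "symbol": tf + "_copy", "chromosome": "chr1", "position": 0,
                "mito": False,
            }])],
            ignore_index=True,
        )
        from sctme import ExpressionMatrix

        m2 = ExpressionMatrix(counts, gene_meta, m.cell_meta)
        normalize_log(m2)
        targets = [t for (r, t) in truth.grn_edges if r == tf][:5]
        # all features per split: the duplicates then compete head-to-head
        base = infer_grn(m2, targets, truth.tf_genes, n_trees=300,
                         max_features=1.0, seed=3)
        dup = infer_grn(m2, targets, truth.tf_genes + [tf + "_copy"],
                        n_trees=300, max_features=1.0, seed=3)
        for t in targets:
            orig = base.edges.query("target == @t and regulator == @tf")["importance"].sum()
            pair = dup.edges[
                (dup.edges["target"] == t)
                & dup.edges["regulator"].isin([tf, tf + "_copy"])
            ]["importance"].sum()
            assert pair == pytest.approx(orig, rel=0.3, abs=0.05)

    def test_constant_target_skipped(self):
        m, truth = prepared(grn_spec(seed=4))
        m.log_layer[m.gene_index([truth.target_genes[0]])[0]] = 0.0
        net = infer_grn(m, truth.target_genes[:3], truth.tf_genes, n_trees=50, seed=4)
        assert truth.target_genes[0] not in set(net.edges["target"])

    def test_too_few_cells_rejected(self):
        m, truth = prepared(grn_spec(seed=5))
        with pytest.raises(ValueError):
            infer_grn(m, truth.target_genes[:2], truth.tf_genes,
                      cells=np.arange(10), n_trees=10, seed=0)


class TestSubsets:
    def _epi_toy(self):
        # cluster 0 expresses all 4 ligands in every cell; cluster 1 none
        ligands = ["SFTPA1", "ICAM1", "CTGF", "CYR61"]
        counts = np.zeros((6, 40), dtype=int)
        counts[:4, :20] = 3
        counts[4:, :] = 2
        m = toy_matrix(counts, tissues=["tumor"] * 16 + ["normal"] * 4 + ["normal"] * 20)
        m.gene_meta.loc[:3, "symbol"] = ligands
        labels = np.array([0] * 20 + [1] * 20)
        return m, labels, ligands

    def test_toy_split_is_exact(self):
        m, labels, ligands = self._epi_toy()
        cmp_ = split_subsets(m, labels, [0, 1], ligands)
        assert cmp_.qualifying_clusters == [0]
        assert (cmp_.subset[:20] == 1).all() and (cmp_.subset[20:] == 2).all()

    def test_tissue_fractions_reported(self):
        m, labels, ligands = self._epi_toy()
        cmp_ = split_subsets(m, labels, [0, 1], ligands)
        assert cmp_.tissue_fractions.loc["subset1", "tumor"] == pytest.approx(0.8)
        assert cmp_.tissue_fractions.loc["subset2", "normal"] == pytest.approx(1.0)

    def test_detection_threshold_boundary_inclusive(self):
        ligands = ["SFTPA1"]
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :5] = 1  # exactly 25% of cluster cells express the ligand
        counts[1, :] = 2
        m = toy_matrix(counts)
        m.gene_meta.loc[0, "symbol"] = "SFTPA1"
        cmp_ = split_subsets(m, np.zeros(20, dtype=int), [0], ligands,
                             detection_fraction=0.25)
        assert cmp_.qualifying_clusters == [0]

    def test_no_qualifying_cluster_warns(self):
        m, labels, ligands = self._epi_toy()
        m.counts = sp.csr_matrix(np.zeros_like(np.asarray(m.counts.todense())))
        with pytest.warns(UserWarning):
            cmp_ = split_subsets(m, labels, [0, 1], ligands)
        assert (cmp_.subset == 2).all()

    def test_planted_subset_de_recovered_and_permutation_null_empty(self):
        # ligand-positive epithelial population vs a ligand-negative one;
        # the ligands are type-exclusive so only one cluster qualifies
        spec = SyntheticSpec(
            n_cells_per_type={
                "epithelial": {"tumor": 160, "normal": 40},
                "T cell": {"tumor": 40, "normal": 160},
            },
            seed=6,
            lowq_cells={"count": 0},
            lr_channels=[
                ("SFTPA1", "TLR2", "epithelial", "T cell"),
                ("ICAM1", "ITGAM", "epithelial", "T cell"),
                ("CTGF", "ITGAM", "epithelial", "T cell"),
                ("CYR61", "ITGAM", "epithelial", "T cell"),
            ],
            cnv={"regions": [], "malignant_fraction": 0.0},
            trajectory=None,
            grn=None,
        )
        m, truth = prepared(spec)
        ct = truth.cells["cell_type"].to_numpy()
        labels = (ct == "T cell").astype(int)
        ligands = ["SFTPA1", "ICAM1", "CTGF", "CYR61"]
        cmp_ = split_subsets(m, labels, [0, 1], ligands, detection_fraction=0.25)
        assert cmp_.qualifying_clusters == [0]
        cmp_ = subset_de(m, cmp_)
        up = set(cmp_.up_in_subset1)
        # markers of the qualifying population separate the subsets strongly
        assert len(up & set(truth.markers["epithelial"])) >= 5
        # tumor enrichment of the ligand-positive subset is reported
        assert cmp_.tissue_fractions.loc["subset1", "tumor"] == pytest.approx(0.8)
        # permuted subset labels: significant lists collapse
        rng = np.random.default_rng(0)
        cmp_perm = split_subsets(m, labels, [0, 1], ligands)
        cmp_perm.subset = rng.permutation(cmp_perm.subset)
        cmp_perm = subset_de(m, cmp_perm)
        assert len(cmp_perm.up_in_subset1) + len(cmp_perm.down_in_subset1) <= 2

    def test_default_thresholds(self):
        from sctme.subsets import DEFAULT_LFC_CUT, DEFAULT_Q_CUT

        assert DEFAULT_Q_CUT == 0.01
        assert DEFAULT_LFC_CUT == 1.0

    def test_small_subsets_rejected(self):
        m, labels, ligands = self._epi_toy()
        cmp_ = split_subsets(m, labels, [0, 1], ligands)
        cmp_.subset = np.array([1] * 5 + [2] * 35)
        cmp_.cells = np.arange(40)
        with pytest.raises(ValueError):
            subset_de(m, cmp_)
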