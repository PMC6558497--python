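"""Principal-tree trajectories, state DE, transition-state genes."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sctme import (
    assign_fates,
    de_by_state,
    learn_trajectory,
    ordering_genes,
    transition_genes,
)
from sctme.trajectory import natural_spline_basis

from conftest import prepared, trajectory_spec


def truth_labels(truth):
    return truth.cells["cell_type"].astype("category").cat.codes.to_numpy()


def root_mask(truth):
    t = truth.cells
    return ((t["cell_type"] == "CD14+ monocyte") & (t["tissue"] == "normal")).to_numpy()


class TestOrderingGenes:
    def test_planted_cluster_difference_captured(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        planted = set(truth.transition_up) | set(truth.transition_down)
        assert len(planted & set(genes)) >= 0.5 * len(genes)

    def test_budget_bounded_by_clusters(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        labels = truth_labels(truth)
        genes = ordering_genes(m, labels, top_per_cluster=50)
        assert len(genes) <= 50 * np.unique(labels).size

    def test_identical_clusters_error(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        rng = np.random.default_rng(0)
        random_split = rng.integers(0, 2, m.n_cells)
        with pytest.raises(ValueError):
            ordering_genes(m, random_split)


class TestLearnTrajectory:
    def test_linear_pseudotime_recovery(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        rho = spearmanr(tr.pseudotime, truth.cells["pseudotime"]).statistic
        assert abs(rho) >= 0.9
        assert rho > 0  # root anchored at the normal-monocyte end

    def test_reversed_root_reverses_ordering(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        fwd = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        rev_mask = (truth.cells["cell_type"] == "M2 macrophage").to_numpy()
        rev = learn_trajectory(m, genes, root_mask=rev_mask, seed=0)
        rho = spearmanr(fwd.pseudotime, rev.pseudotime).statistic
        assert rho < -0.95

    def test_root_state_is_normal_enriched(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        normal = (truth.cells["tissue"] == "normal").to_numpy()
        fracs = {
            s: normal[tr.state == s].mean()
            for s in np.unique(tr.state)
            if (tr.state == s).sum() >= 20
        }
        assert fracs[tr.root_state] == max(fracs.values())

    def test_states_partition_cells(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        assert tr.state.size == tr.cells.size
        assert tr.pseudotime.min() == 0.0

    def test_pseudotime_invariant_under_cell_duplication(self, linear_trajectory_dataset):
        import scipy.sparse as sp

        from sctme import ExpressionMatrix

        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        rmask = root_mask(truth)
        tr = learn_trajectory(m, genes, root_mask=rmask, seed=0)
        idx = np.repeat(np.arange(m.n_cells), 2)
        cm = m.cell_meta.iloc[idx].copy()
        cm["barcode"] = [f"b{i}" for i in range(len(idx))]
        m2 = ExpressionMatrix(
            m.counts[:, idx], m.gene_meta, cm, log_layer=m.log_layer[:, idx]
        )
        tr2 = learn_trajectory(m2, genes, root_mask=np.repeat(rmask, 2), seed=0)
        rho = spearmanr(tr.pseudotime, tr2.pseudotime[::2]).statistic
        assert rho > 0.98

    def test_empty_root_rule_rejected(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        with pytest.raises(ValueError):
            learn_trajectory(m, genes, root_mask=np.zeros(m.n_cells, bool), seed=0)

    def test_two_branch_assignment(self):
        m, truth = prepared(trajectory_spec(seed=1, n_branches=2))
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=1)
        fates = assign_fates(tr, truth.cells["cell_type"].to_numpy(), "M2 macrophage")
        at1 = set(tr.path_states(fates["AT1"]))
        at2 = set(tr.path_states(fates["AT2"])) if fates["AT2"] is not None else set()
        inferred = np.array(
            [
                "A" if (s in at1 and s not in at2)
                else ("B" if (s in at2 and s not in at1) else "?")
                for s in tr.state
            ]
        )
        tb = truth.cells["branch"].to_numpy()
        post = truth.cells["pseudotime"].to_numpy() > 0.5
        mask = post & np.isin(tb, ["M2 macrophage", "CD1c+ DC"]) & (inferred != "?")
        agree = ((inferred[mask] == "A") == (tb[mask] == "M2 macrophage")).mean()
        assert max(agree, 1 - agree) >= 0.85


class TestStateDE:
    def test_planted_state_effect_detected_and_null_flat(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        res = de_by_state(m, tr).set_index("gene")
        planted = [g for g in truth.transition_up if g in res.index]
        assert (res.loc[planted, "qvalue"] < 0.05).mean() >= 0.9
        # genes without planted structure stay mostly quiet
        roles = (
            set(truth.transition_up)
            | set(truth.transition_down)
            | {g for gs in truth.markers.values() for g in gs}
        )
        null_genes = [g for g in res.index if g not in roles][:200]
        assert res.loc[null_genes, "pvalue"].median() > 0.3

    def test_permuted_states_destroy_significance(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        rng = np.random.default_rng(0)
        tr_perm = tr
        tr_perm.state = rng.permutation(tr.state)
        res = de_by_state(m, tr_perm).set_index("gene")
        planted = [g for g in truth.transition_up if g in res.index]
        assert res.loc[planted, "pvalue"].median() > 0.1


class TestTransitionGenes:
    def test_spline_basis_shape_and_linearity_outside_knots(self):
        x = np.linspace(0, 1, 50)
        basis = natural_spline_basis(x, df=3)
        assert basis.shape == (50, 3)
        assert np.allclose(basis[:, 0], x)

    def test_planted_monotone_genes_detected_with_direction(
        self, linear_trajectory_dataset
    ):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        fates = assign_fates(tr, truth.cells["cell_type"].to_numpy(), "M2 macrophage")
        res = transition_genes(m, tr, fates["AT1"])
        found = {r.gene: r.direction for r in res}
        up_rate = np.mean([found.get(g) == "up" for g in truth.transition_up])
        down_rate = np.mean([found.get(g) == "down" for g in truth.transition_down])
        assert up_rate >= 0.95
        assert down_rate >= 0.9

    def test_constant_gene_not_reported(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        fates = assign_fates(tr, truth.cells["cell_type"].to_numpy(), "M2 macrophage")
        m2 = m.copy()
        m2.counts = m2.counts.tolil()
        m2.counts[0] = 3  # flat, expression independent of pseudotime
        m2.counts = m2.counts.tocsr()
        res = transition_genes(m2, tr, fates["AT1"], genes=[m2.gene_meta["symbol"][0]])
        assert all(r.gene != m2.gene_meta["symbol"][0] for r in res)

    def test_results_sorted_and_thresholded(self, linear_trajectory_dataset):
        m, truth = linear_trajectory_dataset
        genes = ordering_genes(m, truth_labels(truth))
        tr = learn_trajectory(m, genes, root_mask=root_mask(truth), seed=0)
        fates = assign_fates(tr, truth.cells["cell_type"].to_numpy(), "M2 macrophage")
        res = transition_genes(m, tr, fates["AT1"])
        ps = [r.pvalue for r in res]
        assert ps == sorted(ps)
        assert all(r.pvalue < 0.005 and r.qvalue < 0.05 for r in res)
        assert all(r.qvalue >= r.pvalue for r in res)
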