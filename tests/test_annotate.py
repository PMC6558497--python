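"""Pairwise NB differential tests and the marker enrichment score."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from sctme import MarkerCollection, cluster_type_scores, de_test_nb, pair_score
from sctme.annotate import PairwiseDEResult

from conftest import four_type_spec, prepared


def make_de(genes, fcs, padj):
    table = pd.DataFrame(
        {"log2fc": fcs, "pvalue": np.asarray(padj) / 2.0, "padj": padj},
        index=pd.Index(genes, name="gene"),
    )
    return PairwiseDEResult(pair=(0, 1), table=table)


class TestPairScore:
    def test_only_significant_markers_contribute(self):
        de = make_de(["g1", "g2"], [2.0, 1.0], [0.01, 0.20])
        assert pair_score(de, ["g1", "g2"]) == pytest.approx(2.0)

    def test_no_significant_marker_gives_zero(self):
        de = make_de(["g1"], [3.0], [0.50])
        assert pair_score(de, ["g1"]) == 0.0

    def test_signed_sum_admits_negative_fold_changes(self):
        de = make_de(["g1", "g3"], [2.0, -1.5], [0.01, 0.001])
        assert pair_score(de, ["g1", "g3"]) == pytest.approx(0.5)

    def test_positive_only_variant_drops_negative_terms(self):
        de = make_de(["g1", "g3"], [2.0, -1.5], [0.01, 0.001])
        assert pair_score(de, ["g1", "g3"], positive_only=True) == pytest.approx(2.0)

    def test_markers_absent_from_table_are_skipped(self):
        de = make_de(["g1"], [2.0], [0.01])
        assert pair_score(de, ["g1", "not_there"]) == pytest.approx(2.0)

    def test_alpha_monotonicity_never_loses_contributors(self):
        de = make_de(["g1", "g2", "g3"], [1.0, 1.0, 1.0], [0.01, 0.04, 0.20])
        n_at = {
            a: sum(de.table["padj"] < a) for a in (0.02, 0.05, 0.5)
        }
        assert n_at[0.02] <= n_at[0.05] <= n_at[0.5]
        assert pair_score(de, list(de.table.index), alpha=0.5) >= pair_score(
            de, list(de.table.index), alpha=0.02
        )


class TestDETest:
    def test_label_swap_negates_log2fc_exactly(self, small_typed_dataset):
        m, truth = small_typed_dataset
        ct = truth.cells["cell_type"].to_numpy()
        a = np.flatnonzero(ct == "epithelial")
        b = np.flatnonzero(ct == "T cell")
        ab = de_test_nb(m, a, b).table["log2fc"].to_numpy()
        ba = de_test_nb(m, b, a).table["log2fc"].to_numpy()
        assert np.nanmax(np.abs(ab + ba)) == 0.0

    def test_null_pvalues_near_uniform(self, small_typed_dataset):
        m, truth = small_typed_dataset
        ct = truth.cells["cell_type"].to_numpy()
        cells = np.flatnonzero(ct == "T cell")
        rng = np.random.default_rng(0)
        perm = rng.permutation(cells)
        half = len(perm) // 2
        de = de_test_nb(m, perm[:half], perm[half:])
        p = de.table["pvalue"].dropna().to_numpy()
        assert kstest(p, "uniform").statistic < 0.1

    def test_planted_fourfold_difference_recovered(self, small_typed_dataset):
        m, truth = small_typed_dataset
        ct = truth.cells["cell_type"].to_numpy()
        de = de_test_nb(
            m, np.flatnonzero(ct == "epithelial"), np.flatnonzero(ct == "T cell")
        )
        fc = de.table.loc[truth.markers["epithelial"], "log2fc"]
        assert abs(float(fc.median()) - 2.0) < 0.5
        padj = de.table.loc[truth.markers["epithelial"], "padj"]
        assert (padj < 0.05).all()

    def test_all_zero_genes_excluded_from_testing(self):
        from conftest import toy_matrix

        counts = np.random.default_rng(0).poisson(3, size=(10, 30)) + 1
        counts[4] = 0
        m = toy_matrix(counts)
        de = de_test_nb(m, np.arange(15), np.arange(15, 30))
        assert np.isnan(de.table.iloc[4]["pvalue"])
        assert np.isnan(de.table.iloc[4]["padj"])

    def test_groups_must_have_three_cells(self, small_typed_dataset):
        m, _ = small_typed_dataset
        with pytest.raises(ValueError):
            de_test_nb(m, np.array([0, 1]), np.arange(10, 30))


class TestClusterScores:
    def test_decomposition_identity_to_machine_precision(self, small_typed_dataset):
        m, truth = small_typed_dataset
        labels = truth.cells["cell_type"].astype("category").cat.codes.to_numpy()
        scores = cluster_type_scores(m, labels, truth.markers)
        clusters = scores.scores.index
        for i in clusters:
            for t in scores.scores.columns:
                total = sum(
                    scores.pair_scores[(i, j, t)] for j in clusters if j != i
                )
                assert scores.scores.loc[i, t] == pytest.approx(total, abs=1e-12)

    def test_planted_markers_identify_every_cluster(self, small_typed_dataset):
        m, truth = small_typed_dataset
        ct = truth.cells["cell_type"]
        labels = ct.astype("category").cat.codes.to_numpy()
        code_to_type = dict(enumerate(ct.astype("category").cat.categories))
        scores = cluster_type_scores(m, labels, truth.markers)
        for cl, assigned in scores.assignment.items():
            assert assigned == code_to_type[cl]

    def test_score_invariant_to_markers_absent_from_matrix(self, small_typed_dataset):
        m, truth = small_typed_dataset
        labels = truth.cells["cell_type"].astype("category").cat.codes.to_numpy()
        base = cluster_type_scores(m, labels, truth.markers)
        padded = {t: gs + ["NOT_A_GENE"] for t, gs in truth.markers.items()}
        same = cluster_type_scores(m, labels, padded)
        pd.testing.assert_frame_equal(base.scores, same.scores)

    def test_identical_marker_sets_tie_and_flag(self, small_typed_dataset):
        m, truth = small_typed_dataset
        labels = truth.cells["cell_type"].astype("category").cat.codes.to_numpy()
        dup = {"A": truth.markers["epithelial"], "B": truth.markers["epithelial"]}
        scores = cluster_type_scores(m, labels, dup)
        assert (scores.scores["A"] == scores.scores["B"]).all()
        assert scores.ambiguous.any()

    def test_single_cluster_rejected(self, small_typed_dataset):
        m, truth = small_typed_dataset
        with pytest.raises(ValueError):
            cluster_type_scores(m, np.zeros(m.n_cells, dtype=int), truth.markers)

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError):
            MarkerCollection({"t": []})

    def test_marker_collections_load_from_gmt_and_tsv(self, tmp_path):
        from sctme.annotate import markers_from_gmt, markers_from_tsv

        (tmp_path / "m.gmt").write_text("M2 macrophage\tdesc\tMRC1\tMSR1\n")
        (tmp_path / "m.tsv").write_text("M2 macrophage\tMRC1\nM2 macrophage\tMSR1\n")
        assert markers_from_gmt(tmp_path / "m.gmt").sets == {
            "M2 macrophage": ["MRC1", "MSR1"]
        }
        assert markers_from_tsv(tmp_path / "m.tsv").sets == {
            "M2 macrophage": ["MRC1", "MSR1"]
        }
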