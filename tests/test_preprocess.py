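"""Normalization, covariate regression, variable genes, clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from sctme import (
    normalize_log,
    pca_embed_cluster,
    regress_out,
    select_variable_genes,
)
from sctme.qc import mito_fraction

from conftest import four_type_spec, prepared, toy_matrix


class TestNormalizeLog:
    def test_zero_count_maps_to_zero(self):
        m = toy_matrix([[0, 3], [5, 2]])
        normalize_log(m)
        assert m.log_layer[0, 0] == 0.0

    def test_hand_computed_value(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 9
        counts[1, 0] = 10_000 - 9
        m = toy_matrix(counts)
        normalize_log(m)
        assert m.log_layer[0, 0] == pytest.approx(np.log(10.0))

    def test_monotone_within_cell(self):
        m = toy_matrix([[1], [5], [20]])
        normalize_log(m)
        col = m.log_layer[:, 0]
        assert col[0] < col[1] < col[2]

    def test_zero_total_cell_rejected(self):
        m = toy_matrix([[0, 1]])
        with pytest.raises(ValueError):
            normalize_log(m)


class TestRegressOut:
    def test_gene_linear_in_depth_has_null_residuals(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(30, 80)) + 1
        m = toy_matrix(counts)
        normalize_log(m)
        # overwrite one gene's log values with an exact linear function of depth
        depth = m.total_counts().astype(float)
        m.log_layer[0] = 0.3 * depth + 1.0
        resid = regress_out(m)
        assert np.abs(resid[0]).max() < 1e-8

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(3, size=(40, 100)) + 1
        m = toy_matrix(counts, mito_flags=[True] * 3 + [False] * 37)
        normalize_log(m)
        resid = regress_out(m)
        depth = m.total_counts().astype(float)
        mito = mito_fraction(m)
        for cov in (depth, mito):
            cov = (cov - cov.mean()) / cov.std()
            dots = resid @ cov
            assert np.abs(dots).max() < 1e-6

    def test_constant_covariate_dropped_with_warning(self):
        counts = np.full((5, 10), 4)
        m = toy_matrix(counts)
        normalize_log(m)
        with pytest.warns(UserWarning):
            regress_out(m)  # both covariates constant


class TestVariableGenes:
    def test_high_mean_gene_excluded_regardless_of_dispersion(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2, size=(50, 60))
        counts[0] = rng.poisson(60_000, size=60)  # mean log expression > 8
        m = toy_matrix(counts)
        normalize_log(m)
        hvg = select_variable_genes(m, x_high=8.0)
        assert "g1" not in hvg

    def test_planted_high_variance_genes_rank_top_in_their_bins(self):
        from sctme.preprocess import dispersion_zscores

        m, truth = prepared(four_type_spec(seed=13, cells_per_type_per_tissue=60))
        z = dispersion_zscores(m).set_index("symbol")
        markers = [g for gs in truth.markers.values() for g in gs]
        assert z.loc[markers, "zscore"].median() > z["zscore"].median()
        hvg = select_variable_genes(m)
        assert len(set(markers) & set(hvg)) >= 0.8 * len(markers)

    def test_identical_genes_degenerate_z_pass_only_x_rule(self):
        counts = np.full((20, 30), 5)
        counts[:, 0] = 6  # avoid zero-variance pathologies in normalization
        m = toy_matrix(counts)
        normalize_log(m)
        hvg = select_variable_genes(m, x_low=0.0, y_cutoff=0.0)
        assert len(hvg) == 20  # all genes satisfy the x bounds with z = 0


class TestClustering:
    def test_two_well_separated_types_recovered(self):
        # well-separated regime: markers at 8-fold elevation
        spec = four_type_spec(seed=21, cells_per_type_per_tissue=100,
                              marker_log2_boost=3.0, lr_channels=[])
        spec.n_cells_per_type = {
            "epithelial": {"tumor": 100, "normal": 100},
            "T cell": {"tumor": 100, "normal": 100},
        }
        m, truth = prepared(spec)
        cl = pca_embed_cluster(m, embedding="pca", seed=0)
        ari = adjusted_rand_score(truth.cells["cell_type"], cl.labels)
        assert ari >= 0.95

    def test_identical_cells_single_cluster(self):
        counts = np.full((30, 40), 3)
        m = toy_matrix(counts)
        normalize_log(m)
        with pytest.warns(UserWarning):
            cl = pca_embed_cluster(m, embedding="pca", seed=0)
        assert cl.n_clusters == 1

    def test_labels_invariant_to_cell_permutation(self):
        m, _ = prepared(four_type_spec(seed=22, cells_per_type_per_tissue=50))
        cl = pca_embed_cluster(m, embedding="pca", seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_cells)
        m2 = m.subset_cells(perm)
        cl2 = pca_embed_cluster(m2, embedding="pca", seed=0)
        assert adjusted_rand_score(cl.labels[perm], cl2.labels) > 0.99

    def test_pca_reconstruction_error_non_increasing_in_components(self):
        from sklearn.decomposition import PCA

        m, _ = prepared(four_type_spec(seed=23, cells_per_type_per_tissue=40))
        resid = regress_out(m)
        X = resid[m.gene_index(select_variable_genes(m))].T
        errs = []
        for k in (2, 5, 10, 20):
            p = PCA(n_components=k, svd_solver="full").fit(X)
            errs.append(1 - p.explained_variance_ratio_.sum())
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_cluster_count_weakly_monotone_in_resolution_and_hits_planted_T(self):
        m, _ = prepared(four_type_spec(seed=11, cells_per_type_per_tissue=60))
        counts = [
            pca_embed_cluster(m, embedding="pca", seed=0, resolution=r).n_clusters
            for r in (0.1, 0.5, 1.0, 2.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert 4 in counts  # the planted type count appears in the scan

    def test_n_pcs_clamped_with_warning(self):
        m, _ = prepared(four_type_spec(seed=24, cells_per_type_per_tissue=20))
        with pytest.warns(UserWarning):
            cl = pca_embed_cluster(m, n_pcs=10_000, embedding="pca", seed=0)
        assert cl.pcs.shape[1] < 10_000
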