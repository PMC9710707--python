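"""QC, normalization, HVG selection, scaling and embeddings."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from scmoc import (CountMatrix, PairedMultiomeDataset, QCThresholds,
                   log1p_transform, lsi_embed, normalize_total, pca_embed,
                   qc_filter, scale_features, select_hvg_vst)
from scmoc.errors import ParameterError, QCError, StateError, ValidationError
from scmoc.preprocess import subset_to_features, tfidf_transform

from conftest import make_counts


def paired_from(rna_vals, atac_vals):
    return PairedMultiomeDataset(
        make_counts(rna_vals, "rna", feature_prefix="g"),
        make_counts(atac_vals, "atac", feature_prefix="p"),
    )


class TestQC:
    def test_min_counts_drops_empty_cells(self):
        data = paired_from([[0, 0], [60, 40], [150, 50]], np.ones((3, 2)))
        out = qc_filter(data, QCThresholds(min_counts_per_cell=1), QCThresholds())
        assert out.n_cells == 2
        assert list(out.cell_ids) == ["c1", "c2"]

    def test_permissive_thresholds_identity(self, small_paired):
        data, _ = small_paired
        out = qc_filter(data, QCThresholds(), QCThresholds())
        assert out.n_cells == data.n_cells

    def test_cell_failing_one_modality_dropped_from_both(self):
        data = paired_from([[5, 5], [5, 5]], [[0, 0], [1, 1]])
        out = qc_filter(data, QCThresholds(), QCThresholds(min_counts_per_cell=1))
        assert out.n_cells == 1
        assert out.rna.n_cells == out.atac.n_cells == 1

    def test_all_cells_removed_is_an_error(self):
        data = paired_from([[1, 0]], [[1, 0]])
        with pytest.raises(QCError):
            qc_filter(data, QCThresholds(min_counts_per_cell=100), QCThresholds())


class TestNormalize:
    def test_worked_examples(self):
        m = make_counts([[1, 0, 3], [0, 0, 5]])
        out = normalize_total(m)
        assert np.allclose(out.values.toarray(),
                           [[2500, 0, 7500], [0, 0, 10000]])
        assert out.state == "normalized"

    def test_zero_total_cell_named_in_error(self):
        m = make_counts([[1, 1], [0, 0]])
        with pytest.raises(ValidationError, match="c1"):
            normalize_total(m)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_row_sums_hit_scale_factor(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 4, size=(8, 15))
        vals[vals.sum(axis=1) == 0, 0] = 1  # no empty cells
        out = normalize_total(make_counts(vals))
        assert np.allclose(out.cell_totals(), 1e4, rtol=1e-6)

    def test_wrong_state_rejected(self):
        m = make_counts([[1.0]], state="log1p")
        with pytest.raises(StateError):
            normalize_total(m)


class TestLog1p:
    def test_pointwise_values(self):
        m = make_counts([[0.0, np.e - 1, 10000.0]], state="normalized")
        out = log1p_transform(m)
        assert np.allclose(out.values.toarray(),
                           [[0.0, 1.0, np.log(10001.0)]])
        assert out.values[0, 2] == pytest.approx(9.21044, abs=1e-4)

    def test_requires_normalized_state(self):
        with pytest.raises(StateError):
            log1p_transform(make_counts([[1]]))

    def test_shape_and_cell_order_preserved(self, small_paired):
        data, _ = small_paired
        out = log1p_transform(normalize_total(data.rna))
        assert out.shape == data.rna.shape
        assert np.array_equal(out.cell_ids, data.rna.cell_ids)


class TestScale:
    def test_population_sd_zscore(self):
        m = make_counts([[1.0], [2.0], [3.0]], state="log1p")
        out = scale_features(m)
        expected = np.array([-1.22474487, 0.0, 1.22474487])  # sd = sqrt(2/3)
        assert np.allclose(out.dense().ravel(), expected, atol=1e-8)

    def test_constant_feature_maps_to_zero(self):
        m = make_counts([[4.0, 1.0], [4.0, 2.0]], state="log1p")
        out = scale_features(m)
        assert np.all(out.dense()[:, 0] == 0)

    def test_clipping(self):
        col = np.zeros((101, 1))
        col[0, 0] = 1000.0  # extreme outlier, z >> 10
        m = make_counts(col, state="log1p")
        out = scale_features(m, clip=10.0)
        assert out.dense().max() == pytest.approx(10.0)


def _vst_scenario(seed=0):
    """100 cells, 200 genes; genes 0-9 carry an 8-fold group difference."""
    rng = np.random.default_rng(seed)
    n_cells, n_genes = 100, 200
    base = rng.lognormal(0.0, 1.0, n_genes)
    base[:10] = rng.uniform(0.5, 2.0, 10)  # markers moderately expressed
    mu = np.outer(np.ones(n_cells), base)
    mu[np.ix_(np.arange(n_cells) < 50, np.arange(10))] *= 8.0
    X = rng.negative_binomial(10.0, 10.0 / (10.0 + mu)).astype(float)
    return make_counts(X, feature_prefix="g"), X


class TestHVG:
    def test_all_constant_falls_back_to_feature_order(self):
        m = make_counts(np.full((5, 4), 3.0))
        res = select_hvg_vst(m, n_hvg=2)
        assert list(res.selected_feature_ids) == ["f0", "f1"]
        assert np.all(res.standardized_variance == 0)

    def test_group_markers_rank_top_and_match_direct_oracle(self):
        m, X = _vst_scenario()
        res = select_hvg_vst(m, n_hvg=20)
        # independent direct computation of the clipped standardized variance
        mean = X.mean(axis=0)
        clip = np.sqrt(X.shape[0])
        z = np.clip((X - mean) / np.sqrt(res.fitted_trend), -clip, clip)
        oracle = z.var(axis=0, ddof=1)
        assert np.allclose(res.standardized_variance, oracle, atol=1e-9)
        selected = set(res.selected_feature_ids)
        assert all(f"g{j}" in selected for j in range(10))

    def test_n_hvg_equals_n_features_returns_all_sorted(self):
        m, _ = _vst_scenario()
        res = select_hvg_vst(m, n_hvg=200)
        sv = {f: v for f, v in zip(m.feature_ids, res.standardized_variance)}
        vals = [sv[f] for f in res.selected_feature_ids]
        assert vals == sorted(vals, reverse=True)

    def test_invariant_to_cell_and_feature_permutation(self):
        m, _ = _vst_scenario()
        res = select_hvg_vst(m, n_hvg=30)
        rng = np.random.default_rng(5)
        cperm = rng.permutation(m.n_cells)
        fperm = rng.permutation(m.n_features)
        m_perm = CountMatrix(m.values[cperm][:, fperm], m.cell_ids[cperm],
                             m.feature_ids[fperm], "rna")
        res_perm = select_hvg_vst(m_perm, n_hvg=30)
        assert set(res_perm.selected_feature_ids) == set(res.selected_feature_ids)

    def test_n_hvg_too_large_rejected(self):
        m, _ = _vst_scenario()
        with pytest.raises(ParameterError):
            select_hvg_vst(m, n_hvg=201)


class TestPCA:
    def _scaled(self, X):
        m = make_counts(np.asarray(X), state="log1p")
        return scale_features(m, clip=1e9)  # effectively unclipped for oracles

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        m = self._scaled(rng.uniform(0, 4, size=(150, 40)))
        emb = pca_embed(m, n_components=5, seed=0)
        X = m.dense()
        cov = np.cov(X, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(cov)
        proj = (X - X.mean(axis=0)) @ v[:, ::-1][:, :5]
        for j in range(5):
            assert (np.allclose(emb.coords[:, j], proj[:, j], atol=1e-6)
                    or np.allclose(emb.coords[:, j], -proj[:, j], atol=1e-6))

    def test_rank_one_matrix_single_component(self):
        u = np.linspace(-1, 1, 30)[:, None]
        v = np.ones((1, 10))
        m = make_counts(u @ v + 5, state="log1p")
        scaled = scale_features(m, clip=1e9)
        emb = pca_embed(scaled, n_components=3, seed=0)
        var = emb.coords.var(axis=0)
        assert var[0] > 0
        assert np.all(var[1:] < 1e-12 * var[0])

    def test_two_blobs_separate_on_first_component(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 0.1, size=(40, 8)) + np.r_[np.ones(4), np.zeros(4)]
        b = rng.normal(5, 0.1, size=(40, 8)) - np.r_[np.ones(4), np.zeros(4)]
        scaled = self._scaled(np.vstack([a, b]))
        emb = pca_embed(scaled, n_components=2, seed=0)
        assert np.all(np.sign(emb.coords[:40, 0]) != np.sign(emb.coords[40:, 0]))

    def test_identical_rows_identical_coordinates(self):
        row = np.arange(6.0)
        m = make_counts(np.tile(row, (8, 1)), state="log1p")
        emb = pca_embed(scale_features(m), n_components=2, seed=0)
        assert np.allclose(emb.coords, emb.coords[0], atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(9)
        m = self._scaled(rng.uniform(0, 3, size=(50, 20)))
        e1 = pca_embed(m, n_components=4, seed=0)
        e2 = pca_embed(m, n_components=4, seed=1)
        assert np.allclose(e1.coords, e2.coords, atol=1e-8)


class TestLSI:
    def test_idf_weights_rare_peaks_higher(self):
        # one peak open in every cell, one in a single cell
        X = np.array([[5.0, 1.0], [3.0, 0.0], [2.0, 0.0]])
        m = make_counts(X, "atac", state="normalized")
        T = tfidf_transform(m).toarray()
        # cell 0 has both peaks; the rare peak gets the larger weight
        # despite a smaller raw value
        assert T[0, 1] > 0 and T[0, 0] > 0
        idf_common = 3 / (1 + 3)
        idf_rare = 3 / (1 + 1)
        assert idf_rare > idf_common

    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(0.3, size=(60, 120)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        m = make_counts(X, "atac", state="normalized")
        emb = lsi_embed(m, n_components=5, seed=0)
        T = tfidf_transform(m).toarray()
        u, s, vt = np.linalg.svd(T, full_matrices=False)
        proj = u[:, :5] * s[:5]
        for j in range(5):
            assert (np.allclose(emb.coords[:, j], proj[:, j], atol=1e-6)
                    or np.allclose(emb.coords[:, j], -proj[:, j], atol=1e-6))

    def test_orthogonal_blocks_separate(self):
        X = np.zeros((20, 40))
        X[:10, :20] = 1.0
        X[10:, 20:] = 1.0
        m = make_counts(X, "atac", state="normalized")
        emb = lsi_embed(m, n_components=2, seed=0)
        # some component separates the blocks perfectly
        separated = [
            np.ptp(np.sign(emb.coords[:10, j])) == 0
            and np.ptp(np.sign(emb.coords[10:, j])) == 0
            and np.sign(emb.coords[0, j]) != np.sign(emb.coords[-1, j])
            for j in range(2)
        ]
        assert any(separated)

    def test_single_component_is_dominant_singular_vector(self):
        rng = np.random.default_rng(8)
        X = rng.poisson(0.5, size=(30, 50)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        m = make_counts(X, "atac", state="normalized")
        emb = lsi_embed(m, n_components=1, seed=0)
        T = tfidf_transform(m).toarray()
        u, s, vt = np.linalg.svd(T, full_matrices=False)
        ref = u[:, 0] * s[0]
        assert (np.allclose(emb.coords[:, 0], ref, atol=1e-6)
                or np.allclose(emb.coords[:, 0], -ref, atol=1e-6))

    def test_all_zero_cell_rejected(self):
        m = make_counts([[1.0, 0.0], [0.0, 0.0]], "atac", state="normalized")
        with pytest.raises(ValidationError):
            lsi_embed(m, n_components=1, seed=0)

    def test_drop_first_removes_leading_component(self):
        rng = np.random.default_rng(11)
        X = rng.poisson(0.5, size=(40, 60)).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        m = make_counts(X, "atac", state="normalized")
        full = lsi_embed(m, n_components=4, seed=0)
        dropped = lsi_embed(m, n_components=3, seed=0, drop_first=True)
        assert np.allclose(dropped.coords, full.coords[:, 1:4], atol=1e-6)


def test_subset_to_features_orders_columns():
    m = make_counts([[1, 2, 3], [4, 5, 6]], feature_prefix="g")
    out = subset_to_features(m, np.array(["g2", "g0"], dtype=object))
    assert np.allclose(out.dense(), [[3, 1], [6, 4]])
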