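"""Normalisation, batch adjustment, PCA, clustering, single-cell filters."""

import numpy as np
import pandas as pd
import pytest

import vasculome as v
from vasculome.errors import DegenerateInputError, DomainError, ModelError
from vasculome.preprocess import (
    batch_adjust,
    filter_sc_genes,
    hierarchical_cluster,
    log_cpm,
    pca,
    select_ec_cells,
)


def _matrix(values, meta_cols=None, scale="counts"):
    values = pd.DataFrame(values)
    values.index = [f"g{i}" for i in range(values.shape[0])]
    values.columns = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(meta_cols or {}, index=values.columns)
    return v.ExpressionMatrix(values=values, samples=meta, scale=scale)


class TestLogCpm:
    def test_direct_formula(self):
        m = _matrix([[0], [999_999]])
        out = log_cpm(m, pseudocount=0.5)
        lib = 999_999
        assert out.values.iloc[0, 0] == pytest.approx(np.log2(0.5 / (lib + 1) * 1e6))

    def test_depth_invariance_up_to_pseudocount(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(500, (100, 1))
        m1 = _matrix(counts)
        m2 = _matrix(counts * 2)
        d = (log_cpm(m1).values - log_cpm(m2).values).abs()
        assert d.to_numpy().max() < 0.01

    def test_zero_pseudocount_with_zero_count_rejected(self):
        with pytest.raises(DomainError):
            log_cpm(_matrix([[0], [10]]), pseudocount=0.0)

    def test_zero_library_rejected(self):
        with pytest.raises(DegenerateInputError):
            log_cpm(_matrix([[0], [0]]))


class TestBatchAdjust:
    def test_single_batch_is_exact_identity(self, baseline_bulk):
        expr = log_cpm(baseline_bulk)
        expr.samples["batch"] = "b0"
        out = batch_adjust(expr)
        assert (out.values.to_numpy() == expr.values.to_numpy()).all()

    def test_singleton_batch_raises_with_advice(self, baseline_bulk):
        expr = log_cpm(baseline_bulk)
        expr.samples["batch"] = ["b0"] + ["b1"] * (expr.n_samples - 1)
        with pytest.raises(ModelError, match="merge"):
            batch_adjust(expr)

    def test_planted_batch_shift_removed_and_tissue_effect_preserved(self):
        cfg = v.TruthConfig(
            timepoints_h=(0.0,), n_batches=2, batch_shift_log2=1.0, n_reps=6, seed=5
        )
        truth = v.build_truth(cfg)
        expr = log_cpm(v.simulate_bulk(truth, cfg))
        adj = batch_adjust(expr)
        b = expr.samples["batch"]

        def batch_diff(m):
            g0 = m.values.loc[:, b[b == "b0"].index].mean(axis=1)
            g1 = m.values.loc[:, b[b == "b1"].index].mean(axis=1)
            return (g0 - g1).abs()

        assert (batch_diff(adj) < 0.05).mean() >= 0.99

        def tissue_effect(m):
            tt = m.samples["tissue"]
            ec = m.where_samples(compartment="EC")
            genes = truth.signature_genes("brain")
            a = ec.values.loc[genes, ec.samples.index[ec.samples["tissue"] == "brain"]]
            r = ec.values.loc[genes, ec.samples.index[ec.samples["tissue"] != "brain"]]
            return a.mean(axis=1) - r.mean(axis=1)

        assert (tissue_effect(expr) - tissue_effect(adj)).abs().max() < 0.1

    def test_readjustment_changes_little(self):
        """Shrinkage leaves tiny residual batch means, so a second pass is not
        a bit-exact identity; it must still be a near no-op."""
        cfg = v.TruthConfig(timepoints_h=(0.0,), n_batches=2, batch_shift_log2=1.0, seed=6)
        truth = v.build_truth(cfg)
        expr = log_cpm(v.simulate_bulk(truth, cfg))
        adj = batch_adjust(expr)
        adj2 = batch_adjust(adj)
        delta = np.abs(adj2.values.to_numpy() - adj.values.to_numpy())
        removed = np.abs(adj.values.to_numpy() - expr.values.to_numpy())
        assert delta.max() < 0.3
        assert delta.mean() < 0.1 * max(removed.mean(), 1e-9)


class TestPCA:
    def test_rank_one_matrix_concentrates_variance(self):
        u = np.arange(1, 6, dtype=float)[:, None]
        w = np.array([[1.0, 2.0, 3.0]])
        m = _matrix(u @ w, scale="log2")
        res = pca(m, n_components=2)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_loadings_orthonormal(self, rng):
        m = _matrix(rng.normal(size=(50, 20)), scale="log2")
        res = pca(m, n_components=5)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-8)

    def test_reconstruction_and_eigenvalue_oracle(self, rng):
        m = _matrix(rng.normal(size=(50, 20)), scale="log2")
        res = pca(m, n_components=19)
        X = m.values.to_numpy().T
        Xc = X - X.mean(axis=0)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Xc, atol=1e-8)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(Xc.T, bias=True) * Xc.shape[0]))[::-1]
        sv2 = (res.scores.to_numpy() ** 2).sum(axis=0)
        np.testing.assert_allclose(sv2, eigvals[:19], rtol=1e-8, atol=1e-8)

    def test_scores_invariant_to_sample_order_up_to_sign(self, rng):
        m = _matrix(rng.normal(size=(30, 10)), scale="log2")
        perm = rng.permutation(10)
        m2 = m.subset_samples(m.sample_ids[perm])
        r1 = pca(m, 3).scores
        r2 = pca(m2, 3).scores.loc[m.sample_ids]
        for c in r1.columns:
            agree = np.allclose(r1[c], r2[c], atol=1e-8)
            flipped = np.allclose(r1[c], -r2[c], atol=1e-8)
            assert agree or flipped

    def test_too_many_components_raises(self, rng):
        m = _matrix(rng.normal(size=(10, 4)), scale="log2")
        with pytest.raises(DomainError):
            pca(m, n_components=5)


class TestHierarchicalCluster:
    def test_identical_samples_merge_first_at_height_zero(self, rng):
        base = rng.normal(size=(20, 1))
        vals = np.column_stack([base, base, base + 5.0])
        m = _matrix(vals, scale="log2")
        res = hierarchical_cluster(m)
        assert res.linkage[0, 2] == 0.0
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_single_sample_trivial_tree(self, rng):
        m = _matrix(rng.normal(size=(10, 1)), scale="log2")
        res = hierarchical_cluster(m)
        assert res.linkage.shape[0] == 0
        assert res.cut(1).tolist() == [1]

    def test_missing_panel_raises_listing_genes(self, rng):
        m = _matrix(rng.normal(size=(10, 4)), scale="log2")
        with pytest.raises(DomainError, match="zz9"):
            hierarchical_cluster(m, gene_subset=["zz9"])

    def test_recovers_tissues_on_pan_endothelial_panel(
        self, baseline_truth, baseline_bulk
    ):
        from sklearn.metrics import adjusted_rand_score

        ec = log_cpm(baseline_bulk.where_samples(compartment="EC"))
        res = hierarchical_cluster(ec, baseline_truth.pan_endothelial_genes)
        labels = res.cut(3)
        assert adjusted_rand_score(ec.samples["tissue"], labels) == 1.0


class TestSingleCellFilters:
    def test_detection_threshold_rule(self):
        vals = np.zeros((2, 100), dtype=int)
        vals[0, :9] = 1       # 9% of cells: below the 10% cut
        vals[1, :10] = 1      # exactly 10%: kept
        m = _matrix(vals)
        out = filter_sc_genes(m, min_cell_fraction=0.10)
        assert list(out.gene_ids) == ["g1"]

    def test_zero_threshold_keeps_everything(self, rng):
        m = _matrix(rng.poisson(0.2, (30, 40)))
        assert filter_sc_genes(m, 0.0).n_genes == 30

    def test_idempotent(self, rng):
        m = _matrix(rng.poisson(0.5, (50, 60)))
        once = filter_sc_genes(m, 0.10)
        twice = filter_sc_genes(once, 0.10)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_survivor_count_matches_column_count_oracle(self, baseline_truth):
        sc = v.simulate_single_cell(baseline_truth, n_cells_per_tissue=100, seed=2)
        out = filter_sc_genes(sc, 0.10)
        oracle = int(((sc.values.to_numpy() > 0).sum(axis=1) >= 0.10 * sc.n_samples).sum())
        assert out.n_genes == oracle

    def test_double_positive_selection(self):
        vals = np.array([[1, 0, 2], [3, 4, 0], [5, 6, 7]])
        m = _matrix(vals)
        out = select_ec_cells(m, ["g0", "g1"])
        assert list(out.sample_ids) == ["s0"]

    def test_missing_marker_raises_naming_it(self, rng):
        m = _matrix(rng.poisson(1, (5, 5)))
        with pytest.raises(DomainError, match="Pecam1"):
            select_ec_cells(m, ["Pecam1"])

    def test_empty_marker_list_keeps_all_with_warning(self, rng):
        m = _matrix(rng.poisson(1, (5, 5)))
        with pytest.warns(UserWarning):
            out = select_ec_cells(m, [])
        assert out.n_samples == 5

    def test_planted_ec_fraction_recovered(self, baseline_truth):
        sc = v.simulate_single_cell(baseline_truth, n_cells_per_tissue=667, seed=7)
        out = select_ec_cells(sc, baseline_truth.ec_marker_genes)
        frac = out.n_samples / sc.n_samples
        assert frac == pytest.approx(0.80, abs=0.03)
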