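"""Signature derivation: voom weights, one-vs-rest DE, marker rankings,
panels, and single-cell rank-sum markers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import vasculome as v
from vasculome.containers import DifferentialTable, SignatureResult
from vasculome.errors import DomainError, ModelError
from vasculome.io import GeneSetCollection
from vasculome.preprocess import log_cpm, log_normalize_cells
from vasculome.signatures import (
    functional_panels,
    group_design,
    one_vs_rest_de,
    sc_markers_ranksum,
    surface_marker_ranking,
    tissue_signatures,
    top_markers,
    voom_weights,
)


def _table(rows) -> DifferentialTable:
    df = pd.DataFrame(rows, columns=["logFC", "t", "p", "q", "mean_expr"])
    df.index = [f"g{i}" for i in range(len(df))]
    return DifferentialTable(table=df, contrast="test")


class TestVoomWeights:
    def test_weights_positive_and_finite(self, small_matrix):
        X, _ = group_design(small_matrix.samples["tissue"])
        w = voom_weights(small_matrix, X)
        arr = w.to_numpy()
        assert (arr > 0).all() and np.isfinite(arr).all()

    def test_flat_variance_gives_flat_weights(self, rng):
        # identical expected counts for all genes: no mean-variance trend
        genes = pd.Index([f"g{i}" for i in range(2000)])
        cols = pd.Index([f"s{i}" for i in range(8)])
        vals = pd.DataFrame(rng.poisson(200, (2000, 8)), index=genes, columns=cols)
        m = v.ExpressionMatrix(vals, pd.DataFrame({"tissue": ["a"] * 4 + ["b"] * 4}, index=cols))
        X, _ = group_design(m.samples["tissue"])
        w = voom_weights(m, X).to_numpy()
        assert w.max() / w.min() < 2.0

    def test_trend_decreasing_for_count_data(self, baseline_bulk):
        """Negative-binomial counts: log-scale sd falls with abundance, so
        high-abundance observations earn larger weights."""
        ec = baseline_bulk.where_samples(compartment="EC")
        X, _ = group_design(ec.samples["tissue"])
        w = voom_weights(ec, X)
        mean_count = ec.values.mean(axis=1)
        expressed = mean_count > 1
        lo = w[expressed][mean_count[expressed] < mean_count[expressed].median()].mean(axis=1).mean()
        hi = w[expressed][mean_count[expressed] >= mean_count[expressed].median()].mean(axis=1).mean()
        assert hi > lo

    def test_too_few_samples_raises(self, small_matrix):
        tiny = small_matrix.subset_samples(small_matrix.sample_ids[:3])
        X = np.eye(3)
        with pytest.raises(ModelError):
            voom_weights(tiny, X)


class TestOneVsRest:
    def test_group_with_one_sample_raises(self, small_matrix):
        labels = pd.Series(
            ["brain"] + ["lung"] * 8, index=small_matrix.sample_ids
        )
        expr = log_cpm(small_matrix)
        w = pd.DataFrame(1.0, index=expr.gene_ids, columns=expr.sample_ids)
        with pytest.raises(ModelError):
            one_vs_rest_de(expr, w, labels, "brain")

    def test_duplicating_samples_shrinks_pvalues_keeps_logfc(self, small_matrix):
        expr = log_cpm(small_matrix)
        w = pd.DataFrame(1.0, index=expr.gene_ids, columns=expr.sample_ids)
        t1 = one_vs_rest_de(expr, w, small_matrix.samples["tissue"], "brain")
        dup_vals = pd.concat(
            [expr.values, expr.values.add_suffix("_dup")], axis=1
        )
        dup_meta = pd.concat([expr.samples, expr.samples.add_suffix("_dup", axis=0)])
        dup = v.ExpressionMatrix(dup_vals, dup_meta, scale="log2")
        w2 = pd.DataFrame(1.0, index=dup.gene_ids, columns=dup.sample_ids)
        t2 = one_vs_rest_de(dup, w2, dup.samples["tissue"], "brain")
        np.testing.assert_allclose(t2.table["logFC"], t1.table["logFC"], atol=1e-10)
        assert (t2.table["p"] <= t1.table["p"] + 1e-12).all()

    def test_planted_signature_appears_only_in_its_tissue(
        self, baseline_truth, baseline_bulk, baseline_config
    ):
        ec = baseline_bulk.where_samples(compartment="EC")
        sigs = tissue_signatures(ec)
        hits = []
        for t in baseline_config.tissues:
            planted = baseline_truth.signature_genes(t)
            for g in planted:
                in_own = g in set(sigs[t].up_genes)
                in_other = any(
                    g in set(sigs[o].up_genes) for o in baseline_config.tissues if o != t
                )
                hits.append(in_own and not in_other)
        assert np.mean(hits) >= 0.95


class TestTopMarkers:
    def test_empty_significant_set(self):
        t = _table([[2.0, 1.0, 0.5, 0.9, 5.0]])
        assert top_markers(t) == []

    def test_k_larger_than_set_returns_all(self):
        t = _table([[2.0, 5.0, 1e-4, 1e-3, 5.0], [1.0, 4.0, 1e-3, 1e-2, 5.0]])
        assert top_markers(t, k=10) == ["g0", "g1"]

    def test_tie_break_by_q_then_gene_id(self):
        t = _table(
            [
                [2.0, 5.0, 1e-4, 0.020, 5.0],
                [2.0, 5.0, 1e-4, 0.010, 5.0],
                [2.0, 5.0, 1e-4, 0.010, 5.0],
            ]
        )
        assert top_markers(t, k=3) == ["g1", "g2", "g0"]

    def test_negative_logfc_excluded(self):
        t = _table([[-3.0, -9.0, 1e-8, 1e-7, 5.0], [0.5, 3.0, 1e-3, 1e-2, 5.0]])
        assert top_markers(t) == ["g1"]


class TestSurfaceMarkers:
    def _sig(self):
        t = _table(
            [
                [3.0, 9.0, 1e-6, 1e-5, 5.0],
                [2.0, 8.0, 1e-5, 1e-4, 5.0],
                [1.0, 7.0, 1e-4, 1e-3, 5.0],
            ]
        )
        return SignatureResult(
            tissue="brain", table=t, up_genes=["g0", "g1", "g2"],
            top_markers=["g0", "g1", "g2"],
        )

    def test_disjoint_catalog_empty(self):
        assert surface_marker_ranking(self._sig(), ["zz"], k=10) == []

    def test_catalog_equal_to_up_genes_matches_top_markers(self):
        sig = self._sig()
        assert surface_marker_ranking(sig, sig.up_genes, k=10) == sig.top_markers

    def test_planted_surface_markers_rank_within_catalog(self, baseline_truth, baseline_bulk):
        ec = baseline_bulk.where_samples(compartment="EC")
        sigs = tissue_signatures(
            ec, surface_catalog=baseline_truth.surface_catalog, k=1000
        )
        for t in ("brain", "lung", "heart"):
            planted = set(baseline_truth.surface_genes(t))
            ranked = set(sigs[t].surface_markers)
            assert len(ranked & planted) / len(planted) >= 0.9


class TestFunctionalPanels:
    def test_counts_and_empty_intersection(self):
        sig = SignatureResult(
            tissue="brain",
            table=_table([[2.0, 5.0, 1e-4, 1e-3, 5.0]]),
            up_genes=["g0"],
            top_markers=["g0"],
        )
        panels = GeneSetCollection()
        panels.add("hit", ["g0", "other"])
        panels.add("miss", ["absent1", "absent2"])
        counts, tables = functional_panels({"brain": sig}, panels)
        row = counts.set_index(["tissue", "panel"])["count"]
        assert row[("brain", "hit")] == 1 and row[("brain", "miss")] == 0
        assert tables["brain"]["miss"] == []

    def test_panel_of_planted_signature_counts_recall(
        self, baseline_truth, baseline_bulk
    ):
        ec = baseline_bulk.where_samples(compartment="EC")
        sigs = tissue_signatures(ec)
        panels = GeneSetCollection()
        panels.add("brain_truth", baseline_truth.signature_genes("brain"))
        counts, tables = functional_panels(sigs, panels)
        row = counts.set_index(["tissue", "panel"])["count"]
        expected = len(set(sigs["brain"].up_genes) & set(baseline_truth.signature_genes("brain")))
        assert row[("brain", "brain_truth")] == expected


class TestScRankSum:
    def _sc(self, baseline_truth, n=150, seed=3):
        sc = v.simulate_single_cell(baseline_truth, n_cells_per_tissue=n, seed=seed)
        ec = sc.subset_samples(sc.samples.index[sc.samples["cell_type"] == "EC"])
        return log_normalize_cells(ec)

    def test_null_pvalues_uniform_under_permuted_labels(self, baseline_truth):
        sc = self._sc(baseline_truth)
        rng = np.random.default_rng(0)
        perm = pd.Series(
            rng.permutation(sc.samples["tissue"].to_numpy()), index=sc.sample_ids
        )
        tabs = sc_markers_ranksum(sc, perm)
        p = tabs["brain"].table["p"].to_numpy()
        informative = p < 1.0  # constant genes sit at exactly 1
        assert sps.kstest(p[informative], "uniform").pvalue > 0.01

    def test_planted_marker_power(self, baseline_truth):
        sc = self._sc(baseline_truth, n=250)
        tabs = sc_markers_ranksum(sc)
        planted = [
            g for g in baseline_truth.signature_genes("brain")
            if baseline_truth.expected_cpm("brain", "EC", 0.0).loc[g] > 200
        ]
        q = tabs["brain"].table.loc[planted, "q"]
        assert (q < 1e-6).mean() >= 0.9

    def test_constant_gene_flagged_degenerate_with_p_one(self, baseline_truth):
        sc = self._sc(baseline_truth)
        vals = sc.values.copy()
        vals.iloc[0] = 3.0
        sc2 = v.ExpressionMatrix(vals, sc.samples, scale="log2")
        tabs = sc_markers_ranksum(sc2)
        assert tabs["brain"].table.iloc[0]["p"] == 1.0

    def test_too_few_cells_raises(self, baseline_truth):
        sc = self._sc(baseline_truth, n=30)
        keep = list(sc.sample_ids[:1]) + list(sc.sample_ids[-30:])
        sub = sc.subset_samples(keep)
        with pytest.raises(ModelError):
            sc_markers_ranksum(sub)
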