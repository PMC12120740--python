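"""QC, normalisation, Spearman/BH correlation and the joint NMF."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spatialephys import association as assoc
from spatialephys.datatypes import ExpressionMatrix, PipelineError, ValidationError
from spatialephys.synthetic import simulate_low_rank_matrix


def make_expr(counts, genes=None, spots=None, normalized=False):
    counts = np.asarray(counts, dtype=float)
    n_g, n_s = counts.shape
    genes = genes or [f"g{i}" for i in range(n_g)]
    spots = spots or [f"s{i}" for i in range(n_s)]
    return ExpressionMatrix(
        genes=genes,
        spots=spots,
        counts=counts,
        spot_xy=np.zeros((n_s, 2)),
        region=["none"] * n_s,
        normalized=normalized,
    )


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg: adjusted p by explicit step-up."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adj[idx] = running_min
    return adj


class TestQC:
    def test_spot_below_unique_gene_threshold_removed(self):
        n_genes = 1200
        counts = np.zeros((n_genes, 2))
        counts[:999, 0] = 1.0   # 999 unique genes -> filtered
        counts[:1100, 1] = 1.0  # 1100 unique genes -> kept
        out, report = assoc.qc_filter_spots(make_expr(counts), min_unique_genes=1000)
        assert report.removed_spots == ["s0"]
        assert out.spots == ["s1"]

    def test_zero_threshold_keeps_all_spots(self):
        counts = np.array([[1.0, 0.0], [0.0, 2.0]])
        out, _ = assoc.qc_filter_spots(make_expr(counts), min_unique_genes=0)
        assert out.n_spots == 2

    def test_mito_ribo_prefixes_dropped(self):
        counts = np.ones((3, 1))
        expr = make_expr(counts, genes=["mt-Co1", "Rps3", "Bdnf"])
        out, report = assoc.qc_filter_spots(expr, min_unique_genes=0)
        assert out.genes == ["Bdnf"]
        assert set(report.removed_genes) == {"mt-Co1", "Rps3"}

    def test_all_spots_removed_is_pipeline_error(self):
        with pytest.raises(PipelineError):
            assoc.qc_filter_spots(make_expr(np.zeros((10, 3))), min_unique_genes=5)


class TestNormalization:
    def test_spot_totals_scaled_to_median(self):
        counts = np.array([[1.0, 2.0], [3.0, 6.0]])  # totals 4, 8; median 6
        out = assoc.normalize_total_counts(make_expr(counts))
        np.testing.assert_allclose(out.counts.sum(axis=0), [6.0, 6.0])
        np.testing.assert_allclose(out.counts[:, 0], [1.5, 4.5])
        assert out.normalized is True

    def test_equal_totals_is_identity(self):
        counts = np.array([[2.0, 1.0], [2.0, 3.0]])
        out = assoc.normalize_total_counts(make_expr(counts))
        np.testing.assert_allclose(out.counts, counts)

    def test_within_spot_proportions_preserved(self, rng):
        counts = rng.poisson(5.0, (30, 8)).astype(float) + 1.0
        out = assoc.normalize_total_counts(make_expr(counts))
        before = counts / counts.sum(axis=0)
        after = out.counts / out.counts.sum(axis=0)
        np.testing.assert_allclose(after, before, rtol=1e-12)

    def test_zero_total_spot_dropped(self):
        counts = np.array([[1.0, 0.0], [1.0, 0.0]])
        out = assoc.normalize_total_counts(make_expr(counts))
        assert out.spots == ["s0"]


class TestSpearman:
    def _features(self, values, spots):
        return pd.DataFrame({"lfp_rate": values}, index=spots)

    def test_monotone_transform_gives_unit_rho(self):
        f = np.linspace(1.0, 5.0, 12)
        counts = np.vstack([np.exp(f)])
        expr = make_expr(counts, normalized=True)
        table = assoc.correlate_genes_features(
            expr, self._features(f, expr.spots), "lfp_rate"
        )
        assert table.loc[0, "rho"] == pytest.approx(1.0)

    def test_hand_computed_rho_small_n(self):
        # ranks (1,2,3) against (3,1,2): rho = 1 - 6*6/(3*8) = -0.5
        counts = np.zeros((2, 5))
        counts[0] = [3.0, 1.0, 2.0, 4.0, 5.0]
        counts[1] = [1.0, 2.0, 3.0, 4.0, 5.0]
        expr = make_expr(counts, normalized=True)
        feats = self._features([1.0, 2.0, 3.0, 4.0, 5.0], expr.spots)
        table = assoc.correlate_genes_features(expr, feats, "lfp_rate")
        sub = table.set_index("gene")
        # restrict the hand example to the first three spots
        rho = stats.spearmanr([1, 2, 3], [3, 1, 2]).statistic
        assert rho == pytest.approx(-0.5)
        assert sub.loc["g1", "rho"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        counts = rng.poisson(8.0, (40, 60)).astype(float)
        f = rng.normal(size=60)
        expr = make_expr(counts, normalized=True)
        table = assoc.correlate_genes_features(
            expr, self._features(f, expr.spots), "lfp_rate"
        ).set_index("gene")
        for g in range(40):
            oracle = np.corrcoef(
                stats.rankdata(counts[g]), stats.rankdata(f)
            )[0, 1]
            assert table.loc[f"g{g}", "rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_gene_marked_missing(self):
        counts = np.vstack([np.ones(12), np.arange(12.0)])
        expr = make_expr(counts, normalized=True)
        f = np.arange(12.0)
        table = assoc.correlate_genes_features(
            expr, self._features(f, expr.spots), "lfp_rate"
        ).set_index("gene")
        assert np.isnan(table.loc["g0", "rho"])
        assert np.isfinite(table.loc["g1", "p_adj"])

    def test_too_few_spots_rejected(self):
        expr = make_expr(np.ones((2, 4)), normalized=True)
        with pytest.raises(PipelineError):
            assoc.correlate_genes_features(
                expr, self._features([1, 2, 3, 4], expr.spots), "lfp_rate"
            )

    def test_exact_permutation_p_for_tiny_n(self):
        # perfectly monotone gene over 6 spots: exact two-sided p = 2/6!
        counts = np.vstack([np.arange(6.0)])
        expr = make_expr(counts, normalized=True)
        f = np.arange(6.0)
        table = assoc.correlate_genes_features(
            expr, self._features(f, expr.spots), "lfp_rate"
        )
        assert table.loc[0, "p_value"] == pytest.approx(2 / 720)


class TestBenjaminiHochberg:
    def test_hand_example_all_adjust_to_largest(self):
        adj = bh_stepup_oracle([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, 0.04)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1], adj
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_implementation_matches_stepup_oracle(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        p = rng.uniform(0, 1, n)
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], bh_stepup_oracle(p), atol=1e-12
        )


class TestJointMatrix:
    def _setup(self, rng, n_spots=50, n_genes=20, n_sig=10):
        counts = rng.poisson(6.0, (n_genes, n_spots)).astype(float)
        expr = make_expr(counts, normalized=True)
        f = rng.uniform(0.1, 0.9, n_spots)
        feats = pd.DataFrame({"lfp_rate": f}, index=expr.spots)
        corr = pd.DataFrame(
            {
                "gene": expr.genes,
                "rho": 0.5,
                "p_value": 0.001,
                "p_adj": [0.01] * n_sig + [0.9] * (n_genes - n_sig),
                "n_spots": n_spots,
            }
        )
        return expr, feats, corr

    def test_shape_is_spots_by_genes_plus_one(self, rng):
        expr, feats, corr = self._setup(rng)
        v, cols = assoc.build_joint_matrix(expr, corr, feats, "lfp_rate")
        assert v.shape == (50, 11)
        assert cols[-1] == "lfp_rate" and len(cols) == 11

    def test_feature_column_minmax_anchored_to_expression_max(self, rng):
        expr, feats, corr = self._setup(rng)
        v, _ = assoc.build_joint_matrix(expr, corr, feats, "lfp_rate")
        assert v[:, -1].min() == pytest.approx(0.0)
        assert v[:, -1].max() == pytest.approx(v[:, :-1].max())

    def test_spot_permutation_permutes_rows_consistently(self, rng):
        expr, feats, corr = self._setup(rng)
        v1, _ = assoc.build_joint_matrix(expr, corr, feats, "lfp_rate")
        perm = rng.permutation(expr.n_spots)
        expr2 = expr.subset_spots(perm)
        v2, _ = assoc.build_joint_matrix(expr2, corr, feats, "lfp_rate")
        np.testing.assert_allclose(v2, v1[perm])

    def test_no_significant_genes_is_error(self, rng):
        expr, feats, corr = self._setup(rng, n_sig=0)
        with pytest.raises(PipelineError):
            assoc.build_joint_matrix(expr, corr, feats, "lfp_rate")


class TestNMF:
    def test_exact_rank2_recovered(self):
        rng = np.random.default_rng(0)
        v = rng.random((30, 2)) @ rng.random((2, 20))
        model = assoc.fit_nmf(
            v, 2, alpha=0.0, beta=0.0, seed=0, restarts=10, tol=1e-14,
            max_iter=20_000,
        )
        assert model.relative_error <= 1e-6

    def test_full_rank_reconstructs_exactly(self):
        rng = np.random.default_rng(1)
        v = rng.random((8, 6))
        model = assoc.fit_nmf(
            v, 6, alpha=0.0, beta=0.0, seed=0, restarts=5, tol=1e-16,
            max_iter=50_000,
        )
        assert model.recon_error <= 1e-6 * np.linalg.norm(v)

    def test_objective_monotone_nonincreasing(self):
        v, _, _ = simulate_low_rank_matrix(40, 25, 3, noise_sigma=0.2, seed=2)
        model = assoc.fit_nmf(v, 3, alpha=0.1, beta=0.1, seed=0, restarts=2)
        diffs = np.diff(model.objective_history)
        assert (diffs <= 1e-8 * model.objective_history[0]).all()

    def test_factors_nonnegative(self):
        v, _, _ = simulate_low_rank_matrix(30, 20, 3, seed=3)
        model = assoc.fit_nmf(v, 3, seed=0, restarts=2)
        assert model.W.min() >= 0 and model.H.min() >= 0

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            assoc.fit_nmf(np.array([[1.0, -0.1]]), 1)

    def test_separable_factors_recovered(self):
        v, w0, _ = simulate_low_rank_matrix(80, 40, 3, noise_sigma=0.05, seed=4)
        model = assoc.fit_nmf(v, 3, alpha=0.0, beta=0.0, seed=0, restarts=5)
        # match each true factor to its best recovered counterpart
        for r in range(3):
            cors = [
                np.corrcoef(w0[:, r], model.W[:, c])[0, 1] for c in range(3)
            ]
            assert max(cors) >= 0.95

    def test_agrees_with_sklearn_reference(self):
        from sklearn.decomposition import NMF

        v, _, _ = simulate_low_rank_matrix(50, 30, 4, noise_sigma=0.3, seed=5)
        ours = assoc.fit_nmf(v, 4, alpha=0.0, beta=0.0, seed=0, restarts=5)
        ref = NMF(
            n_components=4, init="random", random_state=0, max_iter=2000,
            tol=1e-9,
        ).fit(v)
        ref_err = np.linalg.norm(v - ref.transform(v) @ ref.components_)
        assert ours.recon_error <= ref_err * 1.05


class TestRankSelection:
    def test_constructed_piecewise_linear_break_found(self):
        ranks = np.arange(2, 21, dtype=float)
        errors = np.where(ranks <= 12, 100 - 7 * ranks, 16 - 0.2 * (ranks - 12))
        b = assoc._two_segment_break(ranks, errors)
        assert ranks[b] == 12

    def test_planted_rank_found_on_noisy_matrix(self):
        v, _, _ = simulate_low_rank_matrix(100, 30, 4, noise_sigma=0.3, seed=6)
        p_star, curve = assoc.select_rank_elbow(
            v, 1, 10, alpha=0.0, beta=0.0, seed=6, restarts=3, max_iter=400
        )
        assert p_star == 4
        assert (np.diff(curve["recon_error"]) <= 1e-6).all()  # warm-start nesting

    def test_too_narrow_range_rejected(self):
        with pytest.raises(ValueError):
            assoc.select_rank_elbow(np.ones((5, 5)), 2, 4)
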