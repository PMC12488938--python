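"""Blocked Spearman, Benjamini–Hochberg and the correlated-gene screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from epiquant import (
    ExprSimConfig,
    ExpressionMatrix,
    bh_adjust,
    blocked_spearman,
    correlated_gene_screen,
    gen_expression_matrix,
)


def brute_force_bh(p):
    """Direct step-up definition: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBlockedSpearman:
    def test_monotone_within_blocks_gives_one(self):
        x = np.tile(np.arange(10.0), 3)
        y = x**3 + 1
        blocks = np.repeat([0, 1, 2], 10)
        rho, p = blocked_spearman(x, y, blocks, n_perm=500, seed=0)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_antitone_gives_minus_one(self):
        x = np.tile(np.arange(8.0), 2)
        blocks = np.repeat([0, 1], 8)
        rho, _ = blocked_spearman(x, -x, blocks, n_perm=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_weighted_combination_rule(self):
        # block A: perfect rank agreement (rho=1, n=5); block B: rho=0, n=5
        x = np.concatenate([np.arange(1.0, 6.0), np.arange(1.0, 6.0)])
        y = np.concatenate([np.arange(1.0, 6.0), [2.0, 5.0, 3.0, 1.0, 4.0]])
        blocks = np.repeat(["a", "b"], 5)
        assert spearmanr(x[5:], y[5:]).statistic == pytest.approx(0.0)
        rho, _ = blocked_spearman(x, y, blocks, n_perm=50, seed=0)
        assert rho == pytest.approx((4 * 1.0 + 4 * 0.0) / 8)

    def test_rank_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        blocks = np.repeat([0, 1], 20)
        rho1, _ = blocked_spearman(x, y, blocks, n_perm=50, seed=3)
        rho2, _ = blocked_spearman(np.exp(x), y**3, blocks, n_perm=50, seed=3)
        assert rho1 == pytest.approx(rho2)

    def test_all_blocks_too_small_rejected(self):
        with pytest.raises(ValueError, match="usable block"):
            blocked_spearman([1, 2, 3], [1, 2, 3], ["a", "b", "c"])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="usable block"):
            blocked_spearman(np.ones(10), np.arange(10.0), np.zeros(10))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_known_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(bh_adjust(np.ones(7)), np.ones(7))

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_q_never_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(bh_adjust(p), statsmodels.multipletests(p, method="fdr_bh")[1])


class TestExpressionGenerator:
    def test_matrix_shape_bookkeeping(self):
        cfg = ExprSimConfig(seed=1, n_null_genes=30, n_nanog_corr_genes=4, n_sox2_corr_genes=3)
        expr, truth = gen_expression_matrix(cfg)
        n_cells = len(cfg.stages) * cfg.mice_per_stage * cfg.cells_per_mouse
        assert expr.values.shape == (n_cells, 2 + 4 + 3 + 30)
        assert len(truth["nanog_correlated"]) == 4
        assert len(truth["null"]) == 30

    def test_determinism(self):
        cfg = ExprSimConfig(seed=9, n_null_genes=10)
        a, _ = gen_expression_matrix(cfg)
        b, _ = gen_expression_matrix(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_null_genes_rejected(self):
        with pytest.raises(ValueError, match="null gene"):
            ExprSimConfig(n_null_genes=0)

    def test_planted_gene_calibration(self):
        # within-mouse Spearman vs Nanog should track effect_rho
        vals = []
        for seed in range(8):
            cfg = ExprSimConfig(seed=seed, stages=("E6.5", "E7.5"), mice_per_stage=1,
                                cells_per_mouse=400, n_null_genes=1,
                                n_nanog_corr_genes=3, n_sox2_corr_genes=0)
            expr, truth = gen_expression_matrix(cfg)
            ni = expr.gene_index("Nanog")
            for g in truth["nanog_correlated"]:
                gi = expr.gene_index(g)
                for m in np.unique(expr.cell_mouse):
                    s = expr.cell_mouse == m
                    vals.append(spearmanr(expr.values[s, gi], expr.values[s, ni]).statistic)
        assert np.mean(vals) == pytest.approx(cfg.effect_rho, abs=0.1)

    def test_blocking_removes_mouse_confound(self):
        # no planted signal among nulls, strong mouse intercepts: pooled
        # correlations inflate, within-mouse correlations do not
        cfg = ExprSimConfig(seed=4, n_null_genes=40, n_nanog_corr_genes=1,
                            n_sox2_corr_genes=1, mouse_effect_sd=2.0,
                            stages=("E6.5", "E7.0"), mice_per_stage=4, cells_per_mouse=50)
        expr, truth = gen_expression_matrix(cfg)
        ni = expr.gene_index("Nanog")
        stage = expr.cell_stage == "E6.5"
        pooled, blocked = [], []
        for g in truth["null"]:
            gi = expr.gene_index(g)
            pooled.append(abs(spearmanr(expr.values[stage, gi], expr.values[stage, ni]).statistic))
            rho, _ = blocked_spearman(
                expr.values[stage, gi], expr.values[stage, ni],
                expr.cell_mouse[stage], n_perm=10, seed=0,
            )
            blocked.append(abs(rho))
        assert np.mean(pooled) > 2 * np.mean(blocked)


class TestCorrelatedGeneScreen:
    def test_recovers_planted_sets(self):
        cfg = ExprSimConfig(seed=2, n_null_genes=60, n_nanog_corr_genes=4, n_sox2_corr_genes=4)
        expr, truth = gen_expression_matrix(cfg)
        res = correlated_gene_screen(expr, n_perm=500, seed=0)
        assert set(res.nanog_correlated) == set(truth["nanog_correlated"])
        assert set(res.sox2_correlated) == set(truth["sox2_correlated"])
        assert not set(res.nanog_correlated) & set(res.sox2_correlated)

    def test_min_stages_unsatisfiable_gives_empty_sets(self):
        cfg = ExprSimConfig(seed=3, n_null_genes=20, stages=("E6.5", "E7.0"))
        expr, _ = gen_expression_matrix(cfg)
        res = correlated_gene_screen(expr, min_stages=5, n_perm=100, seed=0)
        assert res.nanog_correlated == [] and res.sox2_correlated == []

    def test_evidence_table_contract(self):
        cfg = ExprSimConfig(seed=5, n_null_genes=10, n_nanog_corr_genes=2, n_sox2_corr_genes=2)
        expr, _ = gen_expression_matrix(cfg)
        res = correlated_gene_screen(expr, n_perm=100, seed=0)
        ev = res.evidence
        n_genes = len(expr.gene_names) - 2
        assert len(ev) == n_genes * len(cfg.stages) * 2  # per stage, per anchor
        assert ((ev["rho"] >= -1) & (ev["rho"] <= 1)).all()
        assert ((ev["p"] > 0) & (ev["p"] <= 1)).all()
        assert (ev["q"] >= ev["p"] - 1e-12).all()

    def test_missing_anchor_rejected(self):
        expr = ExpressionMatrix(
            values=np.random.default_rng(0).normal(size=(20, 2)),
            gene_names=["a", "b"],
            cell_stage=np.repeat(["s1", "s2"], 10),
            cell_mouse=np.repeat(["m1", "m2"], 10),
        )
        with pytest.raises(KeyError):
            correlated_gene_screen(expr, anchors=("Nanog", "Sox2"), n_perm=10)
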