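"""Bayesian blocks, mutual information and partial information decomposition."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiquant import (
    bayesian_blocks,
    discretize,
    mutual_information,
    pid_batch,
    pid_two_source,
)
from epiquant.infodecomp import DiscretizationEdges, default_ncp_prior, joint_counts
from epiquant.synthdata import gen_expression_matrix, ExprSimConfig


def exhaustive_blocks(values, ncp_prior):
    """Enumerate all segmentations of the distinct-value cells; return best edges."""
    v = np.sort(np.asarray(values, dtype=float))
    uniq, counts = np.unique(v, return_counts=True)
    m = len(uniq)
    cell_edges = np.concatenate([[uniq[0]], 0.5 * (uniq[1:] + uniq[:-1]), [uniq[-1]]])
    csum = np.concatenate([[0], np.cumsum(counts)])
    best_score, best_edges = -np.inf, None
    for k in range(m):
        for cps in combinations(range(1, m), k):
            bounds = [0, *cps, m]
            score = 0.0
            for a, b in zip(bounds[:-1], bounds[1:]):
                n_k = csum[b] - csum[a]
                t_k = max(cell_edges[b] - cell_edges[a], 1e-300)
                score += n_k * (np.log(n_k) - np.log(t_k)) - ncp_prior
            if score > best_score:
                best_score, best_edges = score, np.unique([cell_edges[i] for i in bounds])
    return best_score, best_edges


class TestBayesianBlocks:
    def test_constant_data_single_block(self):
        e = bayesian_blocks(np.full(20, 3.5))
        assert e.n_bins == 1
        assert e.edges[0] < 3.5 < e.edges[1]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 10, rng.integers(2, 13))
        ncp = default_ncp_prior(len(v))
        _, oracle_edges = exhaustive_blocks(v, ncp)
        dp = bayesian_blocks(v)
        np.testing.assert_allclose(dp.edges, oracle_edges)

    def test_two_clusters_are_separated(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)])
        edges = bayesian_blocks(v)
        codes = discretize(v, edges)
        # the optimum brackets the empty gap with a sparse bridging block, so a
        # cluster tail point may share it; the cluster cores must separate
        centre_codes = discretize([0.0, 10.0], edges)
        assert centre_codes[0] < centre_codes[1]
        assert np.median(codes[:20]) < np.median(codes[20:])
        assert np.sum(codes[:20] == centre_codes[1]) == 0
        assert np.sum(codes[20:] == centre_codes[0]) == 0

    def test_increasing_penalty_never_adds_blocks(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=100)
        n_blocks = [
            bayesian_blocks(v, ncp_prior=ncp).n_bins for ncp in (0.5, 2.0, 5.0, 20.0, 100.0)
        ]
        assert all(a >= b for a, b in zip(n_blocks, n_blocks[1:]))


class TestDiscretize:
    def test_half_open_convention(self):
        edges = DiscretizationEdges(np.array([0.0, 1.0, 2.0]), ncp_prior=1.0)
        assert discretize([0.0], edges)[0] == 0
        assert discretize([1.0], edges)[0] == 1
        assert discretize([2.0], edges)[0] == 1  # last bin closed

    def test_out_of_span_clamped_with_warning(self):
        edges = DiscretizationEdges(np.array([0.0, 1.0]), ncp_prior=1.0)
        with pytest.warns(UserWarning, match="clamped"):
            codes = discretize([-5.0, 5.0], edges)
        np.testing.assert_array_equal(codes, [0, 0])


class TestMutualInformation:
    def test_independent_joint_zero_bits(self):
        assert mutual_information(np.full((2, 2), 0.25)) == pytest.approx(0.0)

    def test_perfect_dependence_one_bit(self):
        assert mutual_information(np.diag([0.5, 0.5])) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        joint = np.array([[0.4, 0.1], [0.1, 0.4]])
        assert mutual_information(joint) == pytest.approx(0.2781, abs=1e-4)


class TestPIDTwoSource:
    def xor_counts(self):
        c = np.zeros((2, 2, 2))
        for x in (0, 1):
            for y in (0, 1):
                c[x, y, x ^ y] = 0.25
        return c

    def test_xor_is_pure_synergy(self):
        r = pid_two_source(counts=self.xor_counts())
        assert r.synergy == pytest.approx(1.0, abs=1e-12)
        assert r.redundancy == pytest.approx(0.0, abs=1e-12)
        assert r.unique_x == pytest.approx(0.0, abs=1e-12)
        assert r.unique_y == pytest.approx(0.0, abs=1e-12)

    def test_copy_is_pure_unique(self):
        c = np.zeros((2, 2, 2))
        for x in (0, 1):
            for y in (0, 1):
                c[x, y, x] = 0.25
        r = pid_two_source(counts=c)
        assert r.unique_x == pytest.approx(1.0, abs=1e-12)
        assert r.redundancy == r.unique_y == r.synergy == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_is_pure_redundancy(self):
        c = np.zeros((2, 2, 2))
        for x in (0, 1):
            c[x, x, x] = 0.5
        r = pid_two_source(counts=c)
        assert r.redundancy == pytest.approx(1.0, abs=1e-12)
        assert r.synergy == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_additivity_and_bounds_on_random_joints(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 4, size=3))
        c = rng.dirichlet(np.ones(int(np.prod(shape)))).reshape(shape)
        r = pid_two_source(counts=c)
        assert r.redundancy + r.unique_x + r.unique_y + r.synergy == pytest.approx(
            r.mi_joint, abs=1e-12
        )
        assert r.redundancy >= -1e-12
        assert r.unique_x >= -1e-12 and r.unique_y >= -1e-12
        assert r.synergy >= -1e-12
        assert r.redundancy <= min(r.mi_x, r.mi_y) + 1e-12

    def test_xor_from_finite_samples(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, 10_000)
        y = rng.integers(0, 2, 10_000)
        r = pid_two_source(x, y, x ^ y)
        assert r.synergy == pytest.approx(1.0, abs=0.02)

    def test_degenerate_target_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="single bin"):
            r = pid_two_source(counts=np.array([[[0.5], [0.0]], [[0.0], [0.5]]]))
        assert r.mi_joint == 0.0

    def test_continuous_inputs_discretised_internally(self):
        rng = np.random.default_rng(3)
        z = np.concatenate([rng.normal(0, 0.2, 400), rng.normal(5, 0.2, 400)])
        x = z + rng.normal(0, 0.2, 800)
        y = rng.normal(0, 1, 800)  # pure noise
        r = pid_two_source(x, y, z)
        assert r.unique_x > 0.5
        assert r.unique_y < 0.1


@pytest.fixture(scope="module")
def expr():
    cfg = ExprSimConfig(seed=6, n_null_genes=3, n_nanog_corr_genes=2,
                        n_sox2_corr_genes=1, mouse_effect_sd=0.0,
                        anchor_rho=0.95, effect_rho=0.9,
                        stages=("E6.5", "E7.5"), mice_per_stage=1, cells_per_mouse=500)
    return gen_expression_matrix(cfg)[0]


class TestPIDBatch:
    def test_informative_gene_beats_noise_source(self, expr):
        table = pid_batch(expr, ["NanogCorr000"], fixed_source="Null0000", target="Sox2")
        row = table.iloc[0]
        assert row["U_gene"] > row["U_fixed"]

    def test_duplicate_source_is_redundant(self, expr):
        table = pid_batch(expr, ["Nanog"], fixed_source="Nanog", target="Sox2")
        row = table.iloc[0]
        assert row["S"] == pytest.approx(0.0, abs=1e-9)
        assert row["R"] == pytest.approx(row["R"] + row["U_gene"], abs=1e-9)

    def test_shuffled_target_kills_information(self, expr):
        rng = np.random.default_rng(0)
        shuffled = expr.values.copy()
        si = expr.gene_names.index("Sox2")
        shuffled[:, si] = rng.permutation(shuffled[:, si])
        expr2 = type(expr)(shuffled, expr.gene_names, expr.cell_stage, expr.cell_mouse)
        intact = pid_batch(expr, ["Nanog"], fixed_source="NanogCorr000", target="Sox2").iloc[0]
        broken = pid_batch(expr2, ["Nanog"], fixed_source="NanogCorr000", target="Sox2").iloc[0]
        # only plug-in finite-sample bias should remain
        assert broken["I_joint"] < 0.2 * intact["I_joint"]
        assert broken["I_joint"] < 0.15

    def test_joint_source_mode_single_row(self, expr):
        table = pid_batch(
            expr, ["Nanog", "NanogCorr000"], fixed_source="Null0000", target="Sox2",
            joint_sources=True,
        )
        assert len(table) == 1


def test_joint_counts_shape_and_total():
    x = np.array([0, 0, 1, 1])
    y = np.array([0, 1, 0, 1])
    z = np.array([0, 1, 1, 0])
    c = joint_counts(x, y, z)
    assert c.shape == (2, 2, 2)
    assert c.sum() == 4
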