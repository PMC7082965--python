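import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet import (
    pearson_correlation,
    pick_soft_threshold,
    scale_free_fit,
    soft_adjacency,
    threshold_edges,
)
from coexnet.errors import ConstantGeneError, DegenerateFitError
from coexnet.network import _powerlaw_fit


def expr_frame(rows, genes=None):
    rows = np.asarray(rows, float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=genes,
                        columns=[f"s{j}" for j in range(rows.shape[1])])


def two_pass_pearson(x, y):
    """Textbook two-pass formula, independent of numpy.corrcoef."""
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)) * math.sqrt(
        sum((b - my) ** 2 for b in y)
    )
    return num / den


class TestPearsonCorrelation:
    def test_identical_and_negated_rows(self):
        expr = expr_frame([[1, 2, 3, 4], [1, 2, 3, 4], [-1, -2, -3, -4]])
        corr = pearson_correlation(expr)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert corr.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_matches_two_pass_formula(self):
        rows = [[1, 2, 3, 4], [1, 2, 3, 5], [4, 1, 2, 2]]
        corr = pearson_correlation(expr_frame(rows))
        for i in range(3):
            for j in range(i + 1, 3):
                assert corr.iloc[i, j] == pytest.approx(
                    two_pass_pearson(rows[i], rows[j]), abs=1e-12
                )

    def test_constant_row_rejected_with_gene_names(self):
        expr = expr_frame([[1, 2, 3], [5, 5, 5], [2, 1, 0]], ["a", "flat", "c"])
        with pytest.raises(ConstantGeneError) as err:
            pearson_correlation(expr)
        assert err.value.gene_ids == ["flat"]

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(4, 10))
        corr0 = pearson_correlation(expr_frame(base))
        scaled = base.copy()
        scaled[0] = 3.2 * base[0] + 7.0
        assert np.allclose(
            pearson_correlation(expr_frame(scaled)), corr0, atol=1e-12
        )
        flipped = base.copy()
        flipped[0] = -2.0 * base[0] + 1.0
        corr_f = pearson_correlation(expr_frame(flipped))
        assert np.allclose(corr_f.iloc[0, 1:], -corr0.iloc[0, 1:], atol=1e-12)


class TestSoftAdjacency:
    def test_spot_values_match_direct_power_evaluation(self):
        corr = pd.DataFrame(
            [[1.0, 0.9, -0.8], [0.9, 1.0, 1.0], [-0.8, 1.0, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        adj = soft_adjacency(corr, 16)
        assert adj.loc["a", "b"] == pytest.approx(0.9**16, abs=1e-12)
        assert adj.loc["a", "c"] == pytest.approx(0.8**16, abs=1e-12)  # sign dropped
        assert adj.loc["b", "c"] == 1.0
        assert (np.diag(adj) == 0).all()

    def test_invalid_beta(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            soft_adjacency(corr, 0)

    def test_monotone_in_correlation_and_beta(self):
        r = np.linspace(0.1, 0.99, 20)
        for beta in (2, 6, 16):
            a = np.abs(r) ** beta
            assert (np.diff(a) > 0).all()  # larger |r| -> larger adjacency
        a6, a16 = np.abs(r) ** 6, np.abs(r) ** 16
        assert (a16 < a6).all()  # larger beta shrinks sub-unit correlations


class TestScaleFreeFit:
    def test_exact_power_law_gives_r2_of_one(self):
        # isolated connectivity values with frequency proportional to 1/k
        k = np.repeat([1.0, 2.0, 4.0, 8.0, 16.0, 32.0], [64, 32, 16, 8, 4, 2])
        fit = _powerlaw_fit(k, n_bins=32)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-1.0, abs=1e-9)

    def test_preferential_attachment_beats_random_graph(self):
        ba = nx.barabasi_albert_graph(1000, 2, seed=7)
        er = nx.gnp_random_graph(1000, ba.number_of_edges() / (1000 * 999 / 2),
                                 seed=7)
        fit_ba = scale_free_fit(nx.to_numpy_array(ba))
        fit_er = scale_free_fit(nx.to_numpy_array(er))
        assert fit_ba.r_squared >= 0.8
        assert fit_ba.slope < 0
        assert fit_er.r_squared < fit_ba.r_squared

    def test_equal_connectivities_degenerate(self):
        ring = nx.cycle_graph(20)
        with pytest.raises(DegenerateFitError):
            scale_free_fit(nx.to_numpy_array(ring))


class TestPickSoftThreshold:
    def test_single_candidate_grid_returned_with_flag(self, planted):
        fit = pick_soft_threshold(planted["corr"], grid=(1,), target_r2=0.9)
        assert fit.beta == 1
        assert fit.target_met == (fit.r_squared >= 0.9)

    def test_deterministic_across_runs(self, planted):
        a = pick_soft_threshold(planted["corr"])
        b = pick_soft_threshold(planted["corr"])
        assert (a.beta, a.r_squared) == (b.beta, b.r_squared)

    def test_smallest_qualifying_beta_preferred(self):
        # scale-free-ish connectivity: a hub-and-spoke correlation structure
        rng = np.random.default_rng(11)
        hub = rng.normal(size=40)
        rows = [hub]
        for i in range(29):
            lam = rng.uniform(0.1, 0.95)
            rows.append(lam * hub + (1 - lam) * rng.normal(size=40))
        corr = pearson_correlation(expr_frame(rows))
        fit = pick_soft_threshold(corr, grid=tuple(range(1, 21)), target_r2=0.5)
        table = fit.table
        qualifying = table[table["r_squared"] >= 0.5]
        if len(qualifying):
            assert fit.beta == int(qualifying.iloc[0]["beta"])
            assert fit.target_met
        else:
            assert not fit.target_met


class TestThresholdEdges:
    def test_absolute_value_convention(self):
        corr = pd.DataFrame(
            [
                [1.0, 0.71, 0.69, -0.75],
                [0.71, 1.0, 0.0, 0.0],
                [0.69, 0.0, 1.0, 0.0],
                [-0.75, 0.0, 0.0, 1.0],
            ],
            index=list("abcd"), columns=list("abcd"),
        )
        graph = threshold_edges(corr, soft_adjacency(corr, 2), 0.7)
        assert graph.number_of_edges() == 2
        assert graph.has_edge("a", "b") and graph.has_edge("a", "d")
        assert graph["a"]["d"]["correlation"] == -0.75
        assert graph["a"]["d"]["weight"] == pytest.approx(0.75**2)
        signed = threshold_edges(corr, soft_adjacency(corr, 2), 0.7, signed=True)
        assert signed.number_of_edges() == 1

    def test_extreme_thresholds(self, planted):
        corr = planted["corr"]
        adj = soft_adjacency(corr, 6)
        offdiag = np.abs(corr.to_numpy())[np.triu_indices(len(corr), 1)]
        high = threshold_edges(corr, adj, min(0.999999, offdiag.max() + 1e-9))
        assert high.number_of_edges() == 0
        assert high.number_of_nodes() == len(corr)
        low = threshold_edges(corr, adj, 1e-12)
        assert low.number_of_edges() == len(offdiag)

    def test_edge_count_non_increasing_in_threshold(self, planted):
        corr, adj = planted["corr"], soft_adjacency(planted["corr"], 6)
        counts = [
            threshold_edges(corr, adj, t).number_of_edges()
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_gene_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        expr = expr_frame(rng.normal(size=(12, 15)))
        corr = pearson_correlation(expr)
        graph = threshold_edges(corr, soft_adjacency(corr, 4), 0.3)
        perm = rng.permutation(len(expr))
        expr_p = expr.iloc[perm]
        corr_p = pearson_correlation(expr_p)
        graph_p = threshold_edges(corr_p, soft_adjacency(corr_p, 4), 0.3)
        assert set(map(frozenset, graph.edges)) == set(map(frozenset, graph_p.edges))
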