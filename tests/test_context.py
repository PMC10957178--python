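"""Contextualization: degree, neighborhood abnormality, gradients, GCEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphlink import (
    Connectome,
    cell_density_maps,
    connectivity_gradients,
    degree_centrality_rank,
    gen_expression,
    gen_smooth_map,
    gcea_cell_types,
    neighborhood_abnormality,
    neighborhood_correlation,
    spatial_correlation,
)


class TestDegreeRank:
    def test_complete_graph_all_tied(self):
        W = np.ones((6, 6)) - np.eye(6)
        ranks = degree_centrality_rank(Connectome(weights=W))
        assert np.allclose(ranks, 3.5)

    def test_star_hub_has_max_rank(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 0.5
        ranks = degree_centrality_rank(Connectome(weights=W))
        assert ranks[0] == 5

    def test_hand_strength_sums(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.2
        W[1, 2] = W[2, 1] = 0.3
        W[2, 3] = W[3, 2] = 0.5
        # strengths: [0.2, 0.5, 0.8, 0.5]
        ranks = degree_centrality_rank(Connectome(weights=W))
        assert np.allclose(ranks, [1, 2.5, 4, 2.5])

    def test_scale_invariant(self, connectome200):
        r1 = degree_centrality_rank(connectome200)
        r2 = degree_centrality_rank(Connectome(weights=3.7 * connectome200.weights))
        assert np.array_equal(r1, r2)

    def test_negative_weights_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = -1.0
        with pytest.raises(ValueError):
            degree_centrality_rank(Connectome(weights=W))


class TestNeighborhoodAbnormality:
    def test_constant_map_binary_graph(self):
        W = (np.ones((5, 5)) - np.eye(5))
        A = neighborhood_abnormality(Connectome(weights=W), np.full(5, 3.3))
        assert np.allclose(A, 3.3)

    def test_hand_example(self):
        """Node with neighbours C={2,4}, w={0.5,1.5} -> (2*0.5+4*1.5)/2 = 3.5."""
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = 1.5
        C = np.array([0.0, 2.0, 4.0])
        A = neighborhood_abnormality(Connectome(weights=W), C)
        assert A[0] == pytest.approx(3.5)

    def test_linearity_in_weights(self, connectome200, smooth_map200):
        A1 = neighborhood_abnormality(connectome200, smooth_map200)
        A2 = neighborhood_abnormality(
            Connectome(weights=2 * connectome200.weights), smooth_map200
        )
        assert np.allclose(A2, 2 * A1)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = 20
            W = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
            W = np.triu(W, 1)
            W = W + W.T
            C = rng.standard_normal(n)
            A = neighborhood_abnormality(Connectome(weights=W), C)
            for i in range(n):
                neigh = [j for j in range(n) if W[i, j] > 0]
                if not neigh:
                    assert np.isnan(A[i])
                    continue
                expected = sum(C[j] * W[i, j] for j in neigh) / len(neigh)
                assert A[i] == pytest.approx(expected, abs=1e-12)

    def test_isolated_nodes_flagged(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        A = neighborhood_abnormality(Connectome(weights=W), np.arange(4.0))
        assert np.isnan(A[2]) and np.isnan(A[3])

    def test_all_isolated_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_abnormality(Connectome(weights=np.zeros((3, 3))), np.ones(3))


class TestGradients:
    @pytest.fixture
    def two_block_connectome(self):
        rng = np.random.default_rng(1)
        n = 40
        A = 0.05 + 0.02 * rng.random((n, n))
        A[:20, :20] += 0.8
        A[20:, 20:] += 0.8
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        return Connectome(weights=A)

    def test_gradient1_separates_blocks(self, two_block_connectome):
        g1 = connectivity_gradients(two_block_connectome, 2, sparsity=0.5)[:, 0]
        assert (np.sign(g1[:20]) == np.sign(g1[0])).all()
        assert (np.sign(g1[20:]) == -np.sign(g1[0])).all()

    def test_permutation_equivariance(self, two_block_connectome):
        rng = np.random.default_rng(2)
        A = two_block_connectome.weights
        perm = rng.permutation(40)
        g = connectivity_gradients(two_block_connectome, 1, sparsity=0.5)[:, 0]
        gp = connectivity_gradients(
            Connectome(weights=A[np.ix_(perm, perm)]), 1, sparsity=0.5
        )[:, 0]
        assert np.allclose(np.abs(gp), np.abs(g[perm]), atol=1e-8)

    def test_real_and_finite(self, connectome200):
        g = connectivity_gradients(connectome200, 2)
        assert g.shape == (200, 2)
        assert np.all(np.isfinite(g))

    def test_disconnected_rejected(self):
        W = np.zeros((6, 6))
        W[0, 1] = W[1, 0] = W[2, 0] = W[0, 2] = 1.0
        W[3, 4] = W[4, 3] = W[5, 3] = W[3, 5] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            connectivity_gradients(Connectome(weights=W), 1, sparsity=0.0)


class TestSpatialCorrelation:
    def test_self_correlation(self, smooth_map200, geometry200, distances200):
        res = spatial_correlation(
            smooth_map200, smooth_map200, geometry=geometry200,
            distances=distances200, null_methods=("spin",), n_null=99, seed=0,
        )
        assert res.statistic == pytest.approx(1.0)
        assert res.p["spin"] == pytest.approx(1 / 100)

    def test_negation(self, smooth_map200, geometry200):
        res = spatial_correlation(
            smooth_map200, -smooth_map200, geometry=geometry200,
            null_methods=(), n_null=0,
        )
        assert res.statistic == pytest.approx(-1.0)

    def test_too_few_common_parcels(self, geometry200, smooth_map200):
        b = np.full(200, np.nan)
        b[:5] = 1.0
        with pytest.raises(ValueError):
            spatial_correlation(smooth_map200, b, geometry=geometry200, null_methods=())


class TestNeighborhoodCorrelation:
    def test_rewire_null_detects_true_topology_coupling(self, connectome200):
        """A map generated by network smoothing correlates with its own
        neighborhood abnormality above the rewiring null."""
        rng = np.random.default_rng(3)
        base = rng.standard_normal(200)
        W = connectome200.weights
        smoothed = 0.3 * base + 0.7 * neighborhood_abnormality(connectome200, base)
        res = neighborhood_correlation(connectome200, smoothed, n_null=50, seed=1)
        assert res.statistic > 0.2
        assert res.p["rewire"] <= 0.05


class TestCellDensity:
    def test_identical_genes(self):
        g = np.array([1.0, 2, 3, 4])
        expr = pd.DataFrame({"g1": g, "g2": g})
        cat = pd.DataFrame({"gene": ["g1", "g2"], "category": ["A", "A"]})
        out = cell_density_maps(expr, cat)
        z = (g - g.mean()) / g.std(ddof=1)
        assert np.allclose(out["A"], z)

    def test_opposite_genes_cancel(self):
        g = np.array([1.0, 2, 3, 4])
        expr = pd.DataFrame({"g1": g, "g2": -g})
        cat = pd.DataFrame({"gene": ["g1", "g2"], "category": ["A", "A"]})
        out = cell_density_maps(expr, cat)
        assert np.allclose(out["A"], 0.0, atol=1e-12)

    def test_hand_three_gene_average(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 3))
        expr = pd.DataFrame(X, columns=["a", "b", "c"])
        cat = pd.DataFrame({"gene": ["a", "b", "c"], "category": ["A"] * 3})
        out = cell_density_maps(expr, cat)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(out["A"], Z.mean(axis=1), atol=1e-12)

    def test_missing_genes_warned_and_skipped(self):
        expr = pd.DataFrame({"a": [1.0, 2, 3]})
        cat = pd.DataFrame({"gene": ["a", "ghost"], "category": ["A", "A"]})
        with pytest.warns(RuntimeWarning):
            out = cell_density_maps(expr, cat)
        assert list(out.columns) == ["A"]


class TestGcea:
    def test_perfect_category_maximal_z(self, geometry100):
        effect = gen_smooth_map(geometry100, 40.0, seed=0)
        expr = pd.DataFrame(
            {f"g{i}": effect for i in range(3)} | {"n1": np.random.default_rng(1).standard_normal(100),
                                                   "n2": np.random.default_rng(2).standard_normal(100)},
            index=geometry100.parcel_id,
        )
        cat = pd.DataFrame(
            {"gene": ["g0", "g1", "g2", "n1", "n2"],
             "category": ["hit", "hit", "hit", "noise", "noise"]}
        )
        out = gcea_cell_types(effect, expr, cat, geometry=geometry100,
                              n_surrogates=99, seed=3)
        assert out.loc["hit", "z"] == pytest.approx(np.arctanh(1 - 1e-7), rel=1e-6)
        assert out.loc["hit", "q"] == out["q"].min()

    def test_planted_categories_recovered(self, geometry100):
        sig = gen_smooth_map(geometry100, 50.0, seed=11)
        expr, cat = gen_expression(
            geometry100, 10, 20, signal_map=sig, signal_categories={"cat00", "cat01"},
            signal_weight=1.5, seed=12,
        )
        out = gcea_cell_types(sig, expr, cat, geometry=geometry100,
                              n_surrogates=200, seed=13)
        assert set(out.index[out["significant"]]) == {"cat00", "cat01"}

    def test_small_category_skipped(self, geometry100):
        effect = gen_smooth_map(geometry100, 40.0, seed=0)
        expr = pd.DataFrame(
            np.random.default_rng(0).standard_normal((100, 3)),
            columns=["a", "b", "c"], index=geometry100.parcel_id,
        )
        cat = pd.DataFrame({"gene": ["a", "b", "c"], "category": ["A", "A", "B"]})
        with pytest.warns(RuntimeWarning):
            out = gcea_cell_types(effect, expr, cat, geometry=geometry100,
                                  n_surrogates=20, seed=1)
        assert list(out.index) == ["A"]

    def test_category_mean_aggregation_mode(self, geometry100):
        sig = gen_smooth_map(geometry100, 50.0, seed=21)
        expr, cat = gen_expression(
            geometry100, 4, 10, signal_map=sig, signal_categories={"cat00"},
            signal_weight=2.0, seed=22,
        )
        out = gcea_cell_types(sig, expr, cat, geometry=geometry100,
                              n_surrogates=100, seed=23,
                              aggregation="category_mean")
        assert out["z"].idxmax() == "cat00"
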