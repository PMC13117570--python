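"""Residual GCN layers, omics encoders, expression bank, augmentation."""

import numpy as np
import pytest

from mgnn.encoders import (
    AugmentationConfig,
    ExpressionInteractionBank,
    OmicsEncoder,
    ResidualGCNLayer,
    augment,
)
from mgnn.nn import Tensor

from conftest import graph_from_edges, random_graph


class TestResidualGCNLayer:
    def _layer(self, d, rng):
        layer = ResidualGCNLayer(d, d, rng)
        layer.linear.b.data[:] = 0
        layer.conv.b.data[:] = 0
        return layer

    def test_triangle_identity_weights_hand_computation(self, triangle, rng):
        """H = I3, W_L = W_c = I: output is ReLU(I) + ReLU((1/3)J) = I + J/3."""
        layer = self._layer(3, rng)
        layer.linear.W.data = np.eye(3)
        layer.conv.W.data = np.eye(3)
        out = layer(Tensor(np.eye(3)), triangle.norm_adjacency)
        assert np.allclose(out.data, np.eye(3) + np.ones((3, 3)) / 3, atol=1e-12)

    def test_zero_convolution_path_reduces_to_node_wise_map(self, triangle, rng):
        layer = self._layer(3, rng)
        layer.conv.W.data[:] = 0
        H = rng.normal(size=(3, 3))
        out = layer(Tensor(H), triangle.norm_adjacency)
        assert np.allclose(out.data, np.maximum(H @ layer.linear.W.data, 0))

    def test_zero_linear_path_reduces_to_convolution(self, triangle, rng):
        layer = self._layer(3, rng)
        layer.linear.W.data[:] = 0
        H = rng.normal(size=(3, 3))
        expected = np.maximum(triangle.norm_adjacency @ H @ layer.conv.W.data, 0)
        assert np.allclose(layer(Tensor(H), triangle.norm_adjacency).data, expected)


class TestOmicsEncoder:
    def test_wrong_block_width_rejected(self, triangle, rng):
        enc = OmicsEncoder(16, rng)
        with pytest.raises(ValueError, match="width"):
            enc(Tensor(np.zeros((3, 8))), triangle.norm_adjacency)

    def test_node_permutation_equivariance(self, rng):
        g = random_graph(10, 0.3, rng)
        enc = OmicsEncoder(16, rng, hidden1=8, hidden2=12)
        X = rng.normal(size=(10, 16))
        out = enc(Tensor(X), g.norm_adjacency).data
        perm = rng.permutation(10)
        S_perm = g.norm_adjacency.toarray()[np.ix_(perm, perm)]
        import scipy.sparse as sp
        out_perm = enc(Tensor(X[perm]), sp.csr_matrix(S_perm)).data
        assert np.allclose(out_perm, out[perm], atol=1e-10)

    def test_identical_parameters_and_inputs_give_identical_outputs(self, rng):
        g = random_graph(8, 0.3, rng)
        e1 = OmicsEncoder(16, np.random.default_rng(7), hidden1=8, hidden2=12)
        e2 = OmicsEncoder(16, np.random.default_rng(7), hidden1=8, hidden2=12)
        X = rng.normal(size=(8, 16))
        assert np.array_equal(e1(Tensor(X), g.norm_adjacency).data,
                              e2(Tensor(X), g.norm_adjacency).data)

    def test_zero_convolution_weights_make_topology_irrelevant(self, rng):
        g1 = random_graph(12, 0.3, rng)
        g2 = random_graph(12, 0.3, rng)
        assert g1.edges != g2.edges
        enc = OmicsEncoder(16, rng, hidden1=8, hidden2=12)
        for layer in enc.layers:
            layer.conv.W.data[:] = 0
            layer.conv.b.data[:] = 0
        X = rng.normal(size=(12, 16))
        assert np.allclose(enc(Tensor(X), g1.norm_adjacency).data,
                           enc(Tensor(X), g2.norm_adjacency).data)


class TestExpressionBank:
    def test_zero_view_mlps_leave_only_fuse_bias(self, triangle, rng):
        bank = ExpressionInteractionBank(rng, hidden1=8, hidden2=12)
        for mlp in bank.view_mlps:
            for lin in (mlp.fc1, mlp.fc2):
                lin.W.data[:] = 0
                lin.b.data[:] = 0
        bank.fuse.b.data = rng.normal(size=12)
        out = bank(Tensor(rng.normal(size=(3, 16))), triangle.norm_adjacency)
        assert np.allclose(out.data, bank.fuse.b.data[None, :].repeat(3, 0))

    def test_view_permutation_with_matching_fuse_blocks_is_invariant(
            self, triangle, rng):
        """Swapping two views while swapping the fuse map's corresponding
        row blocks leaves the fused representation unchanged."""
        bank = ExpressionInteractionBank(rng, hidden1=8, hidden2=12)
        X = Tensor(rng.normal(size=(3, 16)))
        before = bank(X, triangle.norm_adjacency).data.copy()
        bank.view_encoders[0], bank.view_encoders[1] = (
            bank.view_encoders[1], bank.view_encoders[0])
        bank.view_mlps[0], bank.view_mlps[1] = bank.view_mlps[1], bank.view_mlps[0]
        W = bank.fuse.W.data
        blocks = [W[0:12], W[12:24], W[24:36]]
        bank.fuse.W.data = np.concatenate([blocks[1], blocks[0], blocks[2]])
        after = bank(X, triangle.norm_adjacency).data
        assert np.allclose(before, after, atol=1e-12)

    def test_single_isolated_node_depends_only_on_its_features(self, rng):
        g = graph_from_edges(1, set())
        bank = ExpressionInteractionBank(rng, hidden1=8, hidden2=12)
        x1 = bank(Tensor(rng.normal(size=(1, 16))), g.norm_adjacency).data
        assert x1.shape == (1, 12) and np.all(np.isfinite(x1))

    def test_pair_input_widens_encoder_input(self, triangle, rng):
        bank = ExpressionInteractionBank(rng, hidden1=8, hidden2=12,
                                         pair_input=True)
        expr = Tensor(rng.normal(size=(3, 16)))
        paired = tuple(Tensor(rng.normal(size=(3, 16))) for _ in range(3))
        out = bank(expr, triangle.norm_adjacency, paired)
        assert out.shape == (3, 12)
        with pytest.raises(ValueError, match="paired"):
            bank(expr, triangle.norm_adjacency, None)


class TestAugment:
    def test_zero_rates_are_identity(self, rng):
        g = random_graph(15, 0.3, rng)
        X = rng.normal(size=(15, 64))
        cfg = AugmentationConfig(0.0, 0.0)
        X2, S2 = augment(X, g, cfg, seed=0)
        assert np.array_equal(X2, X)
        assert np.allclose(S2.toarray(), g.norm_adjacency.toarray())

    @pytest.mark.parametrize("bad", [1.0, 1.5, -0.1])
    def test_rates_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            AugmentationConfig(feature_mask_rate=bad)

    def test_edge_drop_count_follows_binomial_expectation(self, rng):
        edges = set()
        while len(edges) < 100:
            i, j = rng.integers(0, 40, 2)
            if i != j:
                edges.add((min(i, j), max(i, j)))
        g = graph_from_edges(40, edges)
        cfg = AugmentationConfig(0.0, 0.3)
        n_seeds = 400
        survivors = []
        for s in range(n_seeds):
            _, S2 = augment(np.zeros((40, 64)), g, cfg, seed=s)
            survivors.append((S2.toarray() > 0).sum() - 40)  # minus self-loops
        mean_surv = np.mean(survivors) / 2  # each edge counted twice
        sd = np.sqrt(100 * 0.3 * 0.7)
        assert abs(mean_surv - 70) < 3 * sd / np.sqrt(n_seeds)

    def test_feature_mask_zeroes_expected_fraction(self, rng):
        g = random_graph(30, 0.2, rng)
        X = np.ones((30, 64))
        X2, _ = augment(X, g, AugmentationConfig(0.25, 0.0), seed=3)
        frac = (X2 == 0).mean()
        assert abs(frac - 0.25) < 0.03

    def test_augmented_operator_is_renormalized(self, rng):
        g = random_graph(25, 0.3, rng)
        _, S2 = augment(np.zeros((25, 64)), g,
                        AugmentationConfig(0.0, 0.5), seed=9)
        from _oracles import dense_normalized_adjacency
        A2 = (S2.toarray() > 0).astype(float) - np.eye(25)
        # recover the augmented 0/1 adjacency, then renormalize densely
        assert np.allclose(S2.toarray(), dense_normalized_adjacency(A2),
                           atol=1e-10)

    def test_reproducible_under_seed(self, rng):
        g = random_graph(20, 0.3, rng)
        X = rng.normal(size=(20, 64))
        cfg = AugmentationConfig(0.2, 0.2)
        X1, S1 = augment(X, g, cfg, seed=42)
        X2, S2 = augment(X, g, cfg, seed=42)
        assert np.array_equal(X1, X2) and (S1 != S2).nnz == 0
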