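"""Structural-metric oracles, walk-bias checks, residual enhancement."""

import numpy as np
import pytest

from mgnn.enhancement import (
    EnhancementBundle,
    ExtraMLP,
    StructuralFeatures,
    WalkEmbeddings,
    WalkParams,
    enhance,
    generate_walks,
    node2vec_embed,
    structural_features,
)
from mgnn.nn import Tensor

from _oracles import (
    brute_betweenness,
    brute_closeness,
    brute_clustering,
    brute_core_number,
    brute_eigenvector,
    brute_pagerank,
)
from conftest import graph_from_edges, random_graph


class TestStructuralFeatures:
    def test_star_closed_forms(self, star5):
        sf = structural_features(star5).values
        assert sf[0, 0] == 4                      # center degree
        assert np.isclose(sf[0, 1], 1.0)          # center betweenness
        assert np.allclose(sf[1:, 4], 0.0)        # leaf clustering

    def test_triangle_symmetry(self, triangle):
        sf = structural_features(triangle).values
        assert np.allclose(sf[:, 0], 2)
        assert np.allclose(sf[:, 4], 1.0)
        assert np.allclose(sf[:, 5], 1 / 3, atol=1e-8)

    def test_path_core_and_betweenness(self, path3):
        sf = structural_features(path3).values
        assert np.allclose(sf[:, 6], 1)           # all cores 1
        assert np.isclose(sf[1, 1], 1.0)          # middle node betweenness

    @pytest.mark.parametrize("seed", range(10))
    def test_all_seven_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(6, 31))
        g = random_graph(n, 0.2, rng)
        sf = structural_features(g).values
        A = g.adjacency.toarray()
        deg = A.sum(axis=1)
        expected = np.column_stack([
            deg,
            brute_betweenness(g.edges, n),
            brute_closeness(g.edges, n),
            brute_eigenvector(A),
            brute_clustering(g.edges, n),
            brute_pagerank(A),
            brute_core_number(g.edges, n),
        ])
        assert np.abs(sf - expected).max() < 1e-6

    def test_pagerank_sums_to_one(self, rng):
        g = random_graph(40, 0.1, rng)
        sf = structural_features(g).values
        assert abs(sf[:, 5].sum() - 1.0) < 1e-8

    def test_isolated_node_gets_zero_centralities(self):
        g = graph_from_edges(4, {(0, 1), (1, 2)})   # node 3 isolated
        sf = structural_features(g).values
        assert sf[3, 0] == 0 and sf[3, 4] == 0


class TestWalks:
    def test_uniform_transition_frequencies_when_unbiased(self):
        """p = q = 1: next-step frequencies from a degree-3 node are ~1/3."""
        g = graph_from_edges(4, {(0, 1), (0, 2), (0, 3)})
        params = WalkParams(p=1, q=1, walk_length=5, walks_per_node=2500)
        walks = generate_walks(g, params, seed=5)
        counts = np.zeros(4)
        for w in walks:
            for a, b in zip(w[:-1], w[1:]):
                if a == 0:
                    counts[b] += 1
        total = counts.sum()
        assert total > 1e4
        from scipy.stats import chisquare
        stat, p_val = chisquare(counts[1:])
        assert p_val > 0.01

    def test_large_q_suppresses_outward_steps_on_path(self):
        """On a path a-b-c-d with q -> inf, a walk at b coming from a never
        continues outward to c."""
        g = graph_from_edges(4, {(0, 1), (1, 2), (2, 3)})
        params = WalkParams(p=1, q=1e6, walk_length=20, walks_per_node=200)
        walks = generate_walks(g, params, seed=7)
        outward = total = 0
        for w in walks:
            for t, v, x in zip(w[:-2], w[1:-1], w[2:]):
                # transitions where x is not t and not a neighbor of t
                nbrs_t = {j for i, j in g.edges if i == t} | \
                         {i for i, j in g.edges if j == t}
                total += 1
                if x != t and x not in nbrs_t:
                    outward += 1
        assert total > 500
        assert outward / total < 1e-3

    def test_same_seed_identical_embeddings(self):
        g = graph_from_edges(12, {(i, (i + 1) % 12) for i in range(12)}
                             | {(i, (i + 3) % 12) for i in range(12)})
        params = WalkParams(walk_length=10, walks_per_node=3, dimensions=8,
                            window=3, seed=4)
        e1 = node2vec_embed(g, params)
        e2 = node2vec_embed(g, params)
        assert np.array_equal(e1.values, e2.values)

    def test_isolated_node_still_gets_embedding(self):
        g = graph_from_edges(5, {(0, 1), (1, 2), (2, 3)})   # node 4 isolated
        params = WalkParams(walk_length=8, walks_per_node=4, dimensions=6,
                            window=3, seed=1)
        emb = node2vec_embed(g, params)
        assert emb.values.shape == (5, 6)
        assert np.all(np.isfinite(emb.values))

    def test_connected_nodes_get_non_degenerate_embeddings(self):
        g = graph_from_edges(10, {(i, (i + 1) % 10) for i in range(10)})
        emb = node2vec_embed(g, WalkParams(walk_length=20, walks_per_node=5,
                                           dimensions=8, window=4, seed=2))
        norms = np.linalg.norm(emb.values, axis=1)
        assert (norms > 1e-8).all()


class TestEnhance:
    def test_zero_mlp_is_identity_on_fused(self, rng):
        fused = Tensor(rng.normal(size=(6, 12)))
        mlp = ExtraMLP(5, 12, rng)
        for lin in (mlp.fc1, mlp.fc2):
            lin.W.data[:] = 0
            lin.b.data[:] = 0
        out = enhance(fused, rng.normal(size=(6, 5)), mlp)
        assert np.array_equal(out.data, fused.data)

    def test_zero_fused_leaves_pure_mlp_output(self, rng):
        x_extra = rng.normal(size=(6, 5))
        mlp = ExtraMLP(5, 12, rng)
        out = enhance(Tensor(np.zeros((6, 12))), x_extra, mlp)
        expected = mlp(Tensor(x_extra)).data
        assert np.allclose(out.data, expected)

    def test_all_toggles_off_returns_fused_unchanged(self, rng):
        fused = Tensor(rng.normal(size=(4, 8)))
        bundle = EnhancementBundle(
            structural=None, walks=None, teacher_logits=None,
            toggles={"structural": False, "walks": False, "teacher": False})
        assert bundle.x_extra() is None
        out = enhance(fused, bundle.x_extra(), None)
        assert out is fused

    def test_toggling_walks_changes_width_by_d_w(self, rng):
        struct = StructuralFeatures(values=rng.normal(size=(6, 7)))
        walks = WalkEmbeddings(values=rng.normal(size=(6, 16)),
                               params=WalkParams(dimensions=16))
        on = EnhancementBundle(structural=struct, walks=walks,
                               teacher_logits=rng.normal(size=(6, 1)))
        off = EnhancementBundle(structural=struct, walks=walks,
                                teacher_logits=rng.normal(size=(6, 1)),
                                toggles={"structural": True, "walks": False,
                                         "teacher": True})
        assert on.x_extra().shape[1] - off.x_extra().shape[1] == 16
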