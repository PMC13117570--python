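"""Parsing, normalization and fold-safe standardization."""

import numpy as np
import pandas as pd
import pytest

from mgnn import graph_io
from mgnn.graph_io import (
    EdgeListParseError,
    OmicsMatrix,
    align_features,
    apply_standardizer,
    fit_standardizer,
    normalize_adjacency,
    normalized_operator,
    read_edge_list,
    write_edge_list,
)

from _oracles import dense_normalized_adjacency
from conftest import graph_from_edges, random_graph


def _write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadEdgeList:
    def test_dedup_and_self_edge_drop(self, tmp_path):
        g = read_edge_list(_write(tmp_path, "A B\nB A\nA A\nB C\n"))
        assert g.symbols == ["A", "B", "C"]
        assert g.edges == {(0, 1), (1, 2)}

    def test_confidence_threshold_drops_row_and_orphaned_node(self, tmp_path):
        g = read_edge_list(_write(tmp_path, "A B 0.9\nB C 0.3\n"),
                           min_confidence=0.5)
        assert g.symbols == ["A", "B"]
        assert g.edges == {(0, 1)}

    def test_symbols_upper_cased_and_stripped(self, tmp_path):
        g = read_edge_list(_write(tmp_path, " tp53\tbrca1 \n"))
        assert g.symbols == ["TP53", "BRCA1"]

    def test_malformed_row_reports_line_number(self, tmp_path):
        with pytest.raises(EdgeListParseError, match=":2:"):
            read_edge_list(_write(tmp_path, "A B\nC\n"))

    def test_empty_graph_after_filtering_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="empty graph"):
            read_edge_list(_write(tmp_path, "A B 0.1\n"), min_confidence=0.9)

    def test_random_file_against_line_by_line_recount(self, tmp_path, rng):
        lines, nodes, edges = [], set(), set()
        for _ in range(120):
            i, j = rng.integers(0, 50, 2)
            lines.append(f"N{i} N{j}")
            if i != j:     # independent set-based recount
                nodes |= {f"N{i}", f"N{j}"}
                edges.add(tuple(sorted((f"N{i}", f"N{j}"))))
        g = read_edge_list(_write(tmp_path, "\n".join(lines)))
        assert set(g.symbols) >= nodes
        got = {tuple(sorted((g.symbols[i], g.symbols[j]))) for i, j in g.edges}
        assert got == edges

    def test_write_then_reparse_is_idempotent(self, tmp_path, rng):
        g = random_graph(20, 0.2, rng)
        out = tmp_path / "roundtrip.tsv"
        write_edge_list(g, out)
        g2 = read_edge_list(out)
        assert set(g2.symbols) == set(g.symbols)
        sym_edges = {frozenset((g.symbols[i], g.symbols[j])) for i, j in g.edges}
        sym_edges2 = {frozenset((g2.symbols[i], g2.symbols[j])) for i, j in g2.edges}
        assert sym_edges == sym_edges2


class TestNormalizeAdjacency:
    def test_single_isolated_node(self):
        g = graph_from_edges(1, set())
        assert np.allclose(g.norm_adjacency.toarray(), [[1.0]])

    def test_two_nodes_one_edge_all_entries_half(self):
        g = graph_from_edges(2, {(0, 1)})
        assert np.allclose(g.norm_adjacency.toarray(), 0.5)

    def test_triangle_all_entries_one_third(self, triangle):
        assert np.allclose(triangle.norm_adjacency.toarray(), 1 / 3)

    def test_symmetry_and_row_sums(self, rng):
        g = random_graph(30, 0.15, rng)
        S = g.norm_adjacency.toarray()
        assert np.allclose(S, S.T)
        deg = g.degrees()
        for i in range(30):
            closed = [j for j in range(30)
                      if (min(i, j), max(i, j)) in g.edges or j == i]
            expected = sum((1 + deg[j]) ** -0.5 * (1 + deg[i]) ** -0.5
                           for j in closed)
            assert np.isclose(S[i].sum(), expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_dense_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 51))
        g = random_graph(n, 0.2, rng)
        dense = dense_normalized_adjacency(g.adjacency.toarray())
        assert np.abs(g.norm_adjacency.toarray() - dense).max() < 1e-10

    def test_non_binary_adjacency_rejected(self, triangle):
        bad = triangle.adjacency * 2.0
        with pytest.raises(ValueError, match="binary"):
            normalized_operator(bad)


def _table(symbols, rng, permute=True):
    vals = rng.normal(size=(len(symbols), 64))
    order = list(symbols)
    if permute:
        order = [order[i] for i in rng.permutation(len(order))]
    df = pd.DataFrame(vals, columns=[f"f{i}" for i in range(64)])
    df.insert(0, "gene", order)
    lookup = dict(zip(order, vals))
    return df, lookup


class TestAlignFeatures:
    def test_rows_follow_graph_order(self, triangle, rng):
        df, lookup = _table(triangle.symbols, rng)
        _, om = align_features(triangle, df)
        for i, s in enumerate(triangle.symbols):
            assert np.allclose(om.values[i], lookup[s])

    def test_missing_gene_zero_policy(self, triangle, rng):
        df, _ = _table(triangle.symbols[:2], rng, permute=False)
        g, om = align_features(triangle, df, missing_policy="zero")
        assert g.n_nodes == 3
        assert np.all(om.values[2] == 0)

    def test_drop_policy_matches_subgraph_rebuild_oracle(self, rng):
        g = random_graph(100, 0.05, rng)
        keep = g.symbols[:90]
        df, _ = _table(keep, rng)
        g2, om = align_features(g, df, missing_policy="drop")
        assert g2.n_nodes == 90 and om.values.shape == (90, 64)
        # oracle: rebuild from the filtered symbol-level edge list
        keep_set = set(keep)
        expected = {frozenset((g.symbols[i], g.symbols[j]))
                    for i, j in g.edges
                    if g.symbols[i] in keep_set and g.symbols[j] in keep_set}
        got = {frozenset((g2.symbols[i], g2.symbols[j])) for i, j in g2.edges}
        assert got == expected

    def test_low_match_rate_is_hard_error(self, rng):
        g = random_graph(40, 0.1, rng)
        df, _ = _table([f"OTHER{i}" for i in range(40)], rng)
        with pytest.raises(ValueError, match="identifier"):
            align_features(g, df)


class TestStandardizer:
    def test_two_point_column_population_std(self):
        m = OmicsMatrix(np.tile(np.array([[1.0], [3.0]]), (1, 64)))
        stats = fit_standardizer(m, np.array([0, 1]))
        assert np.allclose(stats.means, 2) and np.allclose(stats.stds, 1)

    def test_constant_column_guard(self):
        vals = np.ones((4, 64)) * 7
        stats = fit_standardizer(OmicsMatrix(vals), np.arange(4))
        assert np.allclose(stats.stds, 1)
        out = apply_standardizer(OmicsMatrix(vals), stats)
        assert np.all(out.values == 0)

    def test_training_rows_become_zero_mean_unit_std(self, rng):
        vals = rng.normal(2.0, 3.0, size=(20, 64))
        rows = np.arange(12)
        stats = fit_standardizer(OmicsMatrix(vals), rows)
        out = apply_standardizer(OmicsMatrix(vals), stats)
        assert np.abs(out.values[rows].mean(axis=0)).max() < 1e-10
        assert np.abs(out.values[rows].std(axis=0) - 1).max() < 1e-6

    def test_identity_stats_leave_matrix_unchanged(self, rng):
        vals = rng.normal(size=(5, 64))
        stats = graph_io.StandardizationStats(np.zeros(64), np.ones(64))
        out = apply_standardizer(OmicsMatrix(vals), stats)
        assert np.array_equal(out.values, vals)

    def test_double_standardization_rejected(self, rng):
        vals = rng.normal(size=(5, 64))
        stats = fit_standardizer(OmicsMatrix(vals), np.arange(5))
        out = apply_standardizer(OmicsMatrix(vals), stats)
        with pytest.raises(ValueError, match="already"):
            apply_standardizer(out, stats)

    def test_source_rows_record_leakage_guard(self, rng):
        vals = rng.normal(size=(10, 64))
        train = np.arange(6)
        stats = fit_standardizer(OmicsMatrix(vals), train)
        held_out = set(range(6, 10))
        assert not (stats.source_rows & held_out)

    def test_empty_row_set_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_standardizer(OmicsMatrix(rng.normal(size=(5, 64))),
                             np.array([], dtype=int))
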