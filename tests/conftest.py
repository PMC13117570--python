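import numpy as np
import pytest

from mgnn.graph_io import GeneGraph, build_graph, normalize_adjacency
from mgnn.synthetic import SyntheticSpec, generate


def graph_from_edges(n: int, edges) -> GeneGraph:
    symbols = [f"G{i}" for i in range(n)]
    pairs = {(symbols[min(i, j)], symbols[max(i, j)]) for i, j in edges}
    return normalize_adjacency(build_graph(symbols, pairs))


def random_graph(n: int, p: float, rng: np.random.Generator) -> GeneGraph:
    edges = {(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p}
    # avoid fully isolated nodes so spectral metrics stay well-conditioned
    for i in range(n):
        if not any(i in e for e in edges):
            j = int(rng.integers(n - 1))
            j = j if j < i else j + 1
            edges.add((min(i, j), max(i, j)))
    return graph_from_edges(n, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    return graph_from_edges(3, {(0, 1), (1, 2), (0, 2)})


@pytest.fixture
def star5():
    return graph_from_edges(5, {(0, 1), (0, 2), (0, 3), (0, 4)})


@pytest.fixture
def path3():
    return graph_from_edges(3, {(0, 1), (1, 2)})


@pytest.fixture(scope="session")
def small_instance():
    """120-node planted-signal benchmark shared by slow-ish tests."""
    return generate(SyntheticSpec(n_nodes=120, prevalence=0.08, seed=11))


@pytest.fixture(scope="session")
def medium_instance():
    """600-node planted-signal benchmark at the default 5% prevalence."""
    return generate(SyntheticSpec(n_nodes=600, prevalence=0.05, seed=11))
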