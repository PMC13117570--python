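"""Desk-scale synthetic benchmark instances: a scale-free gene graph, a
four-block omics matrix with planted label-correlated signal, and labels at
~5% prevalence with a planted label--centrality correlation.

Positives are drawn with probability proportional to ``degree**topo_signal``
(hub attachment), and each signal-carrying omics block shifts every one of
its 16 columns by ``signal`` standard deviations for positive nodes.  The
default leaves the CNV block signal-free so that a pure-noise block exists
in every instance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .graph_io import (
    BLOCK_NAMES,
    BLOCK_WIDTH,
    GeneGraph,
    LabelSet,
    OmicsMatrix,
    build_graph,
    normalize_adjacency,
)


@dataclass
class SyntheticSpec:
    n_nodes: int = 1000
    prevalence: float = 0.05
    graph_model: str = "ba"              # "ba" (m edges/node) or "sbm"
    ba_m: int = 3
    sbm_blocks: int = 4
    sbm_p_in: float = 0.05
    sbm_p_out: float = 0.005
    signal: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 0.0)
    topo_signal: float = 0.5
    noise_sd: float = 1.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 0.5:
            raise ValueError("prevalence must lie in (0, 0.5)")
        if self.prevalence * self.n_nodes < 2:
            raise ValueError("infeasible spec: fewer than 2 expected positives")
        if len(self.signal) != len(BLOCK_NAMES):
            raise ValueError("signal needs one effect size per omics block")


@dataclass
class SyntheticInstance:
    graph: GeneGraph
    omics: OmicsMatrix
    labels: LabelSet
    spec: SyntheticSpec
    truth: dict = field(default_factory=dict)


def generate(spec: SyntheticSpec) -> SyntheticInstance:
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    if spec.graph_model == "ba":
        G = nx.barabasi_albert_graph(n, spec.ba_m,
                                     seed=int(rng.integers(2**31)))
    elif spec.graph_model == "sbm":
        sizes = [n // spec.sbm_blocks] * spec.sbm_blocks
        sizes[0] += n - sum(sizes)
        p = np.full((spec.sbm_blocks, spec.sbm_blocks), spec.sbm_p_out)
        np.fill_diagonal(p, spec.sbm_p_in)
        G = nx.stochastic_block_model(sizes, p.tolist(),
                                      seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown graph model {spec.graph_model!r}")
    symbols = [f"G{i:05d}" for i in range(n)]
    pairs = {(symbols[min(u, v)], symbols[max(u, v)]) for u, v in G.edges()}
    graph = normalize_adjacency(build_graph(symbols, pairs))

    # hub-biased positive draw: P(i positive) proportional to deg^topo_signal
    deg = np.maximum(graph.degrees(), 1.0)
    w = deg ** spec.topo_signal
    prob = w / w.sum()
    n_pos = max(2, int(round(spec.prevalence * n)))
    pos_idx = rng.choice(n, size=n_pos, replace=False, p=prob)
    y = np.zeros(n, dtype=int)
    y[pos_idx] = 1

    X = rng.normal(0.0, spec.noise_sd, size=(n, BLOCK_WIDTH * len(BLOCK_NAMES)))
    for b, eff in enumerate(spec.signal):
        if eff:
            cols = slice(b * BLOCK_WIDTH, (b + 1) * BLOCK_WIDTH)
            X[y == 1, cols] += eff * spec.noise_sd

    y_obs = y.copy()
    if spec.label_noise > 0:
        flip = rng.random(n) < spec.label_noise
        y_obs[flip] = 1 - y_obs[flip]

    labels = LabelSet(positives=set(np.where(y_obs == 1)[0].tolist()),
                      negatives=set(np.where(y_obs == 0)[0].tolist()),
                      unlabeled=set())
    return SyntheticInstance(graph=graph, omics=OmicsMatrix(X), labels=labels,
                             spec=spec, truth={"y_true": y})


def write_instance(instance: SyntheticInstance, directory) -> dict[str, Path]:
    """Write edge list, feature table, label lists and spec YAML."""
    from . import graph_io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": directory / "edges.tsv",
        "features": directory / "features.tsv",
        "positives": directory / "positives.txt",
        "negatives": directory / "negatives.txt",
        "spec": directory / "spec.yaml",
    }
    graph_io.write_edge_list(instance.graph, paths["edges"])
    graph_io.write_feature_table(instance.graph, instance.omics, paths["features"])
    for key, idx_set in (("positives", instance.labels.positives),
                         ("negatives", instance.labels.negatives)):
        with open(paths[key], "w") as fh:
            for i in sorted(idx_set):
                fh.write(instance.graph.symbols[i] + "\n")
    spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(instance.spec).items()}
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=False)
    return paths


def read_instance(directory) -> SyntheticInstance:
    from . import graph_io

    directory = Path(directory)
    with open(directory / "spec.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["signal"] = tuple(raw["signal"])
    spec = SyntheticSpec(**raw)
    graph = graph_io.normalize_adjacency(
        graph_io.read_edge_list(directory / "edges.tsv"))
    table = graph_io.read_feature_table(directory / "features.tsv")
    graph, omics = graph_io.align_features(graph, table)
    labels = graph_io.read_labels(graph, directory / "positives.txt",
                                  directory / "negatives.txt")
    return SyntheticInstance(graph=graph, omics=omics, labels=labels, spec=spec)


def instance_hash(instance: SyntheticInstance) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(instance.omics.values).tobytes())
    h.update(str(sorted(instance.graph.edges)).encode())
    h.update(str(sorted(instance.labels.positives)).encode())
    return h.hexdigest()[:16]
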