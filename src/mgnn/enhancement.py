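"""Topology-derived node features: structural metrics, biased-walk
embeddings, and teacher soft labels, injected residually into the fused
representation.

The structural battery is the standard seven-metric set — degree,
normalized betweenness, closeness, eigenvector centrality, local
clustering, PageRank (damping 0.85) and core number.  Walk embeddings are
node2vec-style: second-order random walks with return parameter ``p`` and
in-out parameter ``q`` feed a skip-gram model with negative sampling.
All of these are unsupervised, label-free quantities computed once on the
full graph; standardization happens per training fold downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_io import GeneGraph
from .nn import Module, Tensor

STRUCTURAL_METRICS = (
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
    "clustering",
    "pagerank",
    "core_number",
)


@dataclass
class StructuralFeatures:
    values: np.ndarray                      # N x 7
    metric_names: tuple[str, ...] = STRUCTURAL_METRICS


@dataclass
class WalkParams:
    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 10
    dimensions: int = 32
    epochs: int = 1
    negatives: int = 5
    lr: float = 0.025
    seed: int = 0


@dataclass
class WalkEmbeddings:
    values: np.ndarray                      # N x d_w
    params: WalkParams


@dataclass
class EnhancementBundle:
    """Optional extra feature sources concatenated into X_extra."""

    structural: StructuralFeatures | None = None
    walks: WalkEmbeddings | None = None
    teacher_logits: np.ndarray | None = None   # N x 1
    toggles: dict = field(default_factory=lambda: {
        "structural": True, "walks": True, "teacher": True})

    def x_extra(self) -> np.ndarray | None:
        parts = []
        if self.toggles.get("structural") and self.structural is not None:
            parts.append(self.structural.values)
        if self.toggles.get("walks") and self.walks is not None:
            parts.append(self.walks.values)
        if self.toggles.get("teacher") and self.teacher_logits is not None:
            parts.append(np.asarray(self.teacher_logits).reshape(-1, 1))
        if not parts:
            return None
        return np.concatenate(parts, axis=1)


def _eigenvector_centrality(graph: GeneGraph) -> np.ndarray:
    """Principal eigenvector of the adjacency (Lanczos), unit L2 norm with
    the largest-magnitude entry positive; zero for edgeless graphs."""
    import scipy.sparse.linalg as spla

    A = graph.adjacency
    n = A.shape[0]
    if A.nnz == 0:
        return np.zeros(n)
    if n < 3:
        vals, vecs = np.linalg.eigh(A.toarray())
        v = vecs[:, np.argmax(vals)]
    else:
        v0 = np.ones(n) / np.sqrt(n)
        _, vecs = spla.eigsh(A.astype(float), k=1, which="LA", v0=v0)
        v = vecs[:, 0]
    v = v / np.linalg.norm(v)
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def _to_networkx(graph: GeneGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(graph.n_nodes))
    G.add_edges_from(graph.edges)
    return G


def structural_features(graph: GeneGraph) -> StructuralFeatures:
    """Seven per-node structural metrics in a fixed column order.

    Conventions: betweenness is normalized (networkx convention,
    2/((n-1)(n-2)) scaling); closeness uses the per-component
    (Wasserman–Faust) scaling; eigenvector centrality is the unit-norm
    principal eigenvector of the adjacency; isolated nodes get 0 where a
    metric is undefined.
    """
    G = _to_networkx(graph)
    n = graph.n_nodes
    cols = np.zeros((n, len(STRUCTURAL_METRICS)))
    cols[:, 0] = [G.degree(i) for i in range(n)]
    if n > 2:
        bet = nx.betweenness_centrality(G, normalized=True)
        cols[:, 1] = [bet[i] for i in range(n)]
    clo = nx.closeness_centrality(G)
    cols[:, 2] = [clo[i] for i in range(n)]
    cols[:, 3] = _eigenvector_centrality(graph)
    clu = nx.clustering(G)
    cols[:, 4] = [clu[i] for i in range(n)]
    pr = nx.pagerank(G, alpha=0.85, tol=1e-12, max_iter=1000)
    cols[:, 5] = [pr[i] for i in range(n)]
    core = nx.core_number(G)
    cols[:, 6] = [core[i] for i in range(n)]
    return StructuralFeatures(values=cols)


# -- biased random walks ---------------------------------------------------


def generate_walks(graph: GeneGraph, params: WalkParams,
                   seed: int | None = None) -> list[np.ndarray]:
    """Second-order biased walks; isolated nodes yield length-1 walks.

    For ``p == q == 1`` the walk is first-order (uniform over neighbors)
    and generated fully vectorized across all starts; otherwise the
    node2vec bias rule is applied stepwise: stepping from t via v, the
    unnormalized probability of the next node x is 1/p if x == t, 1 if x
    is a neighbor of t, else 1/q.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    A = graph.adjacency
    indptr, indices = A.indptr, A.indices
    deg = np.diff(indptr)
    n = graph.n_nodes
    starts = np.tile(np.arange(n), params.walks_per_node)
    if params.p == 1.0 and params.q == 1.0:
        cur = starts.copy()
        alive = deg[cur] > 0
        paths = [cur.copy()]
        for _ in range(params.walk_length - 1):
            nxt = cur.copy()
            idx = np.where(alive)[0]
            if idx.size == 0:
                break
            offs = (rng.random(idx.size) * deg[cur[idx]]).astype(np.int64)
            nxt[idx] = indices[indptr[cur[idx]] + offs]
            paths.append(nxt.copy())
            cur = nxt
            alive = deg[cur] > 0
        mat = np.stack(paths, axis=1)
        walks = []
        for r, s in enumerate(starts):
            if deg[s] == 0:
                walks.append(np.array([s]))
            else:
                walks.append(mat[r])
        return walks
    neighbor_sets = [set(indices[indptr[i]:indptr[i + 1]]) for i in range(n)]
    walks = []
    for s in starts:
        walk = [int(s)]
        if deg[s] == 0:
            walks.append(np.array(walk))
            continue
        nbrs = indices[indptr[s]:indptr[s + 1]]
        walk.append(int(nbrs[rng.integers(len(nbrs))]))
        while len(walk) < params.walk_length:
            t, v = walk[-2], walk[-1]
            nbrs = indices[indptr[v]:indptr[v + 1]]
            if len(nbrs) == 0:
                break
            w = np.where(
                nbrs == t, 1.0 / params.p,
                np.where([x in neighbor_sets[t] for x in nbrs], 1.0,
                         1.0 / params.q))
            w = w / w.sum()
            walk.append(int(rng.choice(nbrs, p=w)))
        walks.append(np.array(walk))
    return walks


def _skipgram_pairs(walks: list[np.ndarray], window: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks:
        L = len(walk)
        for off in range(1, window + 1):
            if L <= off:
                continue
            centers.append(walk[:-off])
            contexts.append(walk[off:])
            centers.append(walk[off:])
            contexts.append(walk[:-off])
    c = np.concatenate(centers)
    x = np.concatenate(contexts)
    perm = rng.permutation(len(c))
    return c[perm], x[perm]


def _train_sgns(pairs: tuple[np.ndarray, np.ndarray], n_nodes: int,
                params: WalkParams, counts: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Skip-gram with negative sampling, vectorized minibatch SGD."""
    d = params.dimensions
    W_in = (rng.random((n_nodes, d)) - 0.5) / d
    W_out = np.zeros((n_nodes, d))
    noise = counts.astype(float) ** 0.75
    noise /= noise.sum()
    centers, contexts = pairs
    batch = 8192
    n_pairs = len(centers)
    for epoch in range(params.epochs):
        for lo in range(0, n_pairs, batch):
            c = centers[lo:lo + batch]
            pos = contexts[lo:lo + batch]
            lr = params.lr * max(1e-4, 1 - (epoch * n_pairs + lo)
                                 / (params.epochs * n_pairs))
            vc = W_in[c]                                   # B x d
            neg = rng.choice(n_nodes, size=(len(c), params.negatives), p=noise)
            # positive pairs
            up = W_out[pos]
            gpos = _sig(np.sum(vc * up, axis=1)) - 1.0     # B
            # negative pairs
            un = W_out[neg]                                # B x k x d
            gneg = _sig(np.einsum("bd,bkd->bk", vc, un))   # B x k
            dvc = gpos[:, None] * up + np.einsum("bk,bkd->bd", gneg, un)
            np.add.at(W_in, c, -lr * dvc)
            np.add.at(W_out, pos, -lr * gpos[:, None] * vc)
            np.add.at(W_out.reshape(-1, d), neg.ravel(),
                      -lr * (gneg[:, :, None] * vc[:, None, :]).reshape(-1, d))
    return W_in


def _sig(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def node2vec_embed(graph: GeneGraph, params: WalkParams | None = None
                   ) -> WalkEmbeddings:
    """Biased walks + skip-gram embeddings; deterministic under the seed."""
    if graph.n_nodes == 0:
        raise ValueError("cannot embed an empty graph")
    params = params or WalkParams()
    rng = np.random.default_rng(params.seed)
    walks = generate_walks(graph, params, seed=int(rng.integers(2**31)))
    counts = np.bincount(np.concatenate(walks), minlength=graph.n_nodes)
    counts = np.maximum(counts, 1)
    pairs = _skipgram_pairs(walks, params.window, rng)
    if len(pairs[0]) == 0:   # degenerate graph: no co-occurrence at all
        emb = (rng.random((graph.n_nodes, params.dimensions)) - 0.5) / params.dimensions
        return WalkEmbeddings(values=emb, params=params)
    emb = _train_sgns(pairs, graph.n_nodes, params, counts, rng)
    return WalkEmbeddings(values=emb, params=params)


# -- residual enhancement --------------------------------------------------


class ExtraMLP(Module):
    """One-hidden-layer projection of X_extra into the hidden width."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator,
                 dtype=np.float64):
        from .nn import Linear
        self.fc1 = Linear(d_in, d_h, rng, dtype=dtype)
        self.fc2 = Linear(d_h, d_h, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def enhance(fused: Tensor, x_extra: np.ndarray | Tensor | None,
            mlp_extra: ExtraMLP | None) -> Tensor:
    """H_enhanced = H_fused + MLP_extra(X_extra); identity when no extras."""
    if x_extra is None or mlp_extra is None:
        return fused
    x = x_extra if isinstance(x_extra, Tensor) else Tensor(np.asarray(x_extra))
    return fused + mlp_extra(x)
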