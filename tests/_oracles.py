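"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately naive — dense algebra, explicit
enumeration, power iteration — and never calls the package code paths it
is used to check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


# -- graph operators -------------------------------------------------------


def dense_normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """D^(-1/2) (A + I) D^(-1/2) by dense matrix algebra."""
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    D = np.diag(1.0 / np.sqrt(d))
    return D @ A_hat @ D


# -- structural metrics ----------------------------------------------------


def _bfs(adj: list[list[int]], s: int):
    """Shortest-path counts and distances from s (Brandes' forward pass)."""
    n = len(adj)
    dist = [-1] * n
    sigma = [0.0] * n
    preds: list[list[int]] = [[] for _ in range(n)]
    dist[s], sigma[s] = 0, 1.0
    order = []
    q = deque([s])
    while q:
        v = q.popleft()
        order.append(v)
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                q.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return dist, sigma, preds, order


def brute_betweenness(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    """Normalized betweenness via explicit pair-dependency accumulation."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    bc = np.zeros(n)
    for s in range(n):
        dist, sigma, preds, order = _bfs(adj, s)
        delta = [0.0] * n
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # undirected: each pair counted twice
    if n > 2:
        bc *= 2.0 / ((n - 1) * (n - 2))
    return bc


def brute_closeness(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    """Wasserman–Faust closeness: ((r-1)/(n-1)) * ((r-1)/sum_d)."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    out = np.zeros(n)
    for s in range(n):
        dist, _, _, _ = _bfs(adj, s)
        reach = [d for d in dist if d >= 0]
        r = len(reach)
        total = sum(reach)
        if total > 0 and n > 1:
            out[s] = ((r - 1) / (n - 1)) * ((r - 1) / total)
    return out


def brute_eigenvector(A: np.ndarray, iters: int = 20000) -> np.ndarray:
    """Power iteration on A + I (the shift breaks the +/-lambda symmetry of
    bipartite graphs without changing eigenvectors); unit L2 norm,
    max-entry positive."""
    n = A.shape[0]
    if A.sum() == 0:
        return np.zeros(n)
    A = A + np.eye(n)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        w = A @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return np.zeros(n)
        w /= nrm
        if np.linalg.norm(w - v) < 1e-14:
            v = w
            break
        v = w
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return v


def brute_clustering(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    nbrs = [set() for _ in range(n)]
    for i, j in edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    out = np.zeros(n)
    for v in range(n):
        k = len(nbrs[v])
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(sorted(nbrs[v]), 2)
                    if b in nbrs[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def brute_pagerank(A: np.ndarray, alpha: float = 0.85, iters: int = 10000,
                   tol: float = 1e-14) -> np.ndarray:
    """Power iteration with uniform teleport; dangling mass spread uniformly."""
    n = A.shape[0]
    deg = A.sum(axis=1)
    P = np.zeros((n, n))
    nonzero = deg > 0
    P[nonzero] = A[nonzero] / deg[nonzero, None]
    x = np.ones(n) / n
    for _ in range(iters):
        dangling = x[~nonzero].sum()
        x_new = alpha * (x @ P + dangling / n) + (1 - alpha) / n
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return x


def brute_core_number(edges: set[tuple[int, int]], n: int) -> np.ndarray:
    """Iterative peeling: remove all nodes of degree <= k, increasing k."""
    nbrs = [set() for _ in range(n)]
    for i, j in edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    core = np.zeros(n, dtype=int)
    alive = set(range(n))
    k = 0
    while alive:
        changed = True
        while changed:
            changed = False
            for v in list(alive):
                if len(nbrs[v] & alive) <= k:
                    core[v] = k
                    alive.discard(v)
                    changed = True
        k += 1
    return core


# -- ranking metrics -------------------------------------------------------


def brute_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs concordance with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Explicit precision–recall curve walk over distinct thresholds."""
    thresholds = sorted(set(scores), reverse=True)
    n_pos = int((labels == 1).sum())
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        called = scores >= t
        tp = int(((labels == 1) & called).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap
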