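"""Gene interaction networks, multi-omics feature tables and label lists.

Genes are nodes of an undirected protein--protein interaction (PPI) graph;
per-gene features are a 64-column matrix split into four 16-column omics
blocks (mutation, expression, methylation, CNV -- one scalar per cancer
type per omics).  The propagation operator used by every graph convolution
is the self-looped, symmetrically normalized adjacency
``D^(-1/2) (A + I) D^(-1/2)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

BLOCK_NAMES = ("mutation", "expression", "methylation", "cnv")
BLOCK_WIDTH = 16
N_FEATURES = BLOCK_WIDTH * len(BLOCK_NAMES)


class EdgeListParseError(ValueError):
    """A row of the edge-list file could not be parsed."""


@dataclass
class GeneGraph:
    """An undirected gene graph with its normalized propagation operator.

    ``edges`` stores unordered index pairs ``(i, j)`` with ``i < j`` and no
    self-pairs; ``adjacency`` is the symmetric 0/1 matrix, and
    ``norm_adjacency`` (built by :func:`normalize_adjacency`) the GCN
    operator.
    """

    symbols: list[str]
    edges: set[tuple[int, int]]
    adjacency: sp.csr_matrix
    norm_adjacency: sp.csr_matrix | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.symbols)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


@dataclass
class OmicsMatrix:
    """N x 64 per-gene feature matrix in graph node order."""

    values: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must have {N_FEATURES} columns, "
                f"got shape {self.values.shape}"
            )

    @property
    def block_slices(self) -> dict[str, slice]:
        return {
            name: slice(i * BLOCK_WIDTH, (i + 1) * BLOCK_WIDTH)
            for i, name in enumerate(BLOCK_NAMES)
        }

    def block(self, name: str) -> np.ndarray:
        return self.values[:, self.block_slices[name]]


@dataclass
class LabelSet:
    """Disjoint positive / negative / unlabeled node-index sets."""

    positives: set[int]
    negatives: set[int]
    unlabeled: set[int]

    def __post_init__(self):
        if (self.positives & self.negatives or self.positives & self.unlabeled
                or self.negatives & self.unlabeled):
            raise ValueError("label sets must be pairwise disjoint")

    @property
    def labeled(self) -> np.ndarray:
        return np.array(sorted(self.positives | self.negatives), dtype=int)

    def y(self, idx: np.ndarray) -> np.ndarray:
        """0/1 labels for the given (labeled) node indices."""
        return np.array([1 if i in self.positives else 0 for i in idx], dtype=float)


@dataclass
class StandardizationStats:
    """Per-column mean/std fitted on an explicit training-row set."""

    means: np.ndarray
    stds: np.ndarray
    source_rows: frozenset[int] = field(default_factory=frozenset)


def _canon(symbol: str) -> str:
    return symbol.strip().upper()


def read_edge_list(path, min_confidence: float | None = None) -> GeneGraph:
    """Parse a whitespace/TSV edge list ``geneA geneB [score]`` into a graph.

    Self-edges are dropped, duplicates collapsed; ``#``-prefixed lines are
    comments.  If ``min_confidence`` is given, rows with a third numeric
    column below it are excluded (nodes survive only through surviving rows).
    """
    pairs: set[tuple[str, str]] = set()
    symbols: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected two gene symbols, got {line!r}"
                )
            a, b = _canon(fields[0]), _canon(fields[1])
            if not a or not b:
                raise EdgeListParseError(f"{path}:{lineno}: empty gene symbol")
            if min_confidence is not None:
                if len(fields) < 3:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: confidence filtering requested "
                        "but row has no score column"
                    )
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: bad confidence {fields[2]!r}"
                    ) from exc
                if score < min_confidence:
                    continue
            if a == b:
                continue
            for s in (a, b):
                if s not in seen:
                    seen.add(s)
                    symbols.append(s)
            pairs.add((a, b) if a < b else (b, a))
    if not symbols:
        raise ValueError(f"{path}: empty graph after filtering")
    return build_graph(symbols, pairs)


def build_graph(symbols: list[str], symbol_pairs: set[tuple[str, str]]) -> GeneGraph:
    index = {s: i for i, s in enumerate(symbols)}
    edges = set()
    for a, b in symbol_pairs:
        i, j = index[a], index[b]
        if i != j:
            edges.add((min(i, j), max(i, j)))
    return GeneGraph(symbols=list(symbols), edges=edges,
                     adjacency=_adjacency_from_edges(len(symbols), edges))


def _adjacency_from_edges(n: int, edges: set[tuple[int, int]]) -> sp.csr_matrix:
    if edges:
        rows, cols = zip(*edges)
        rows, cols = np.array(rows), np.array(cols)
        data = np.ones(len(edges), dtype=float)
        A = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
        A = A + A.T
    else:
        A = sp.coo_matrix((n, n), dtype=float)
    return A.tocsr()


def normalize_adjacency(graph: GeneGraph) -> GeneGraph:
    """Attach ``D^(-1/2) (A + I) D^(-1/2)`` with self-loop degrees."""
    graph.norm_adjacency = normalized_operator(graph.adjacency)
    return graph


def normalized_operator(adjacency: sp.spmatrix) -> sp.csr_matrix:
    A = sp.csr_matrix(adjacency, dtype=float)
    if A.nnz and (A.data < 0).any():
        raise ValueError("adjacency must be non-negative")
    if A.nnz and not np.all((A.data == 0) | (A.data == 1)):
        raise ValueError("adjacency must be binary")
    if np.abs(A - A.T).nnz:
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    A_hat = A + sp.identity(n, format="csr")
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return sp.csr_matrix(D @ A_hat @ D)


def align_features(graph: GeneGraph, table: pd.DataFrame,
                   missing_policy: str = "zero") -> tuple[GeneGraph, OmicsMatrix]:
    """Reorder a symbol-keyed feature table to graph node order.

    ``table`` must carry the gene symbol in its first column (or as its
    index) followed by 64 numeric columns.  Genes absent from the table are
    zero-filled (policy ``"zero"``) or removed from the graph together with
    their incident edges (policy ``"drop"``).
    """
    if missing_policy not in ("zero", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if table.index.name is None and table.shape[1] == N_FEATURES + 1:
        table = table.set_index(table.columns[0])
    if table.shape[1] != N_FEATURES:
        raise ValueError(f"feature table must have {N_FEATURES} numeric columns")
    lookup = {_canon(str(s)): row for s, row in
              zip(table.index, table.to_numpy(dtype=float))}
    matched = [s for s in graph.symbols if s in lookup]
    missing = [s for s in graph.symbols if s not in lookup]
    logger.info("align_features: %d matched, %d missing", len(matched), len(missing))
    if len(matched) < 0.5 * graph.n_nodes:
        raise ValueError(
            f"only {len(matched)}/{graph.n_nodes} graph symbols matched the "
            "feature table; likely an identifier-scheme mismatch"
        )
    if missing_policy == "drop" and missing:
        graph = induced_subgraph(graph, matched)
    rows = np.zeros((graph.n_nodes, N_FEATURES))
    for i, s in enumerate(graph.symbols):
        if s in lookup:
            rows[i] = lookup[s]
    return graph, OmicsMatrix(rows)


def induced_subgraph(graph: GeneGraph, keep_symbols: list[str]) -> GeneGraph:
    keep = set(keep_symbols)
    symbols = [s for s in graph.symbols if s in keep]
    old_index = graph.index
    remap = {old_index[s]: k for k, s in enumerate(symbols)}
    edges = {
        (min(remap[i], remap[j]), max(remap[i], remap[j]))
        for i, j in graph.edges
        if i in remap and j in remap
    }
    return GeneGraph(symbols=symbols, edges=edges,
                     adjacency=_adjacency_from_edges(len(symbols), edges))


def fit_standardizer(matrix: OmicsMatrix | np.ndarray,
                     rows: np.ndarray) -> StandardizationStats:
    """Per-column mean/std (population, ddof=0) over ``rows`` only.

    Zero-variance columns get std 1 so their standardized values become 0.
    """
    values = matrix.values if isinstance(matrix, OmicsMatrix) else np.asarray(matrix)
    rows = np.asarray(rows, dtype=int)
    if rows.size == 0:
        raise ValueError("cannot fit a standardizer on an empty row set")
    sub = values[rows]
    means = sub.mean(axis=0)
    stds = sub.std(axis=0, ddof=0)
    stds = np.where(stds > 0, stds, 1.0)
    return StandardizationStats(means=means, stds=stds,
                                source_rows=frozenset(rows.tolist()))


def apply_standardizer(matrix: OmicsMatrix, stats: StandardizationStats) -> OmicsMatrix:
    """Z-score all rows with training-fold statistics."""
    if matrix.standardized:
        raise ValueError("matrix is already standardized")
    return OmicsMatrix((matrix.values - stats.means) / stats.stds, standardized=True)


def standardize_array(values: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    return (values - stats.means) / stats.stds


def read_labels(graph: GeneGraph, positives_path, negatives_path) -> LabelSet:
    """Read one-symbol-per-line positive/negative lists; rest is unlabeled."""
    index = graph.index

    def load(path) -> set[int]:
        out = set()
        with open(path) as fh:
            for line in fh:
                s = _canon(line)
                if s and not s.startswith("#") and s in index:
                    out.add(index[s])
        return out

    pos = load(positives_path)
    neg = load(negatives_path) - pos
    unl = set(range(graph.n_nodes)) - pos - neg
    return LabelSet(positives=pos, negatives=neg, unlabeled=unl)


def write_edge_list(graph: GeneGraph, path) -> None:
    with open(path, "w") as fh:
        for i, j in sorted(graph.edges):
            fh.write(f"{graph.symbols[i]}\t{graph.symbols[j]}\n")


def write_feature_table(graph: GeneGraph, matrix: OmicsMatrix, path) -> None:
    cols = [f"{name}_{k}" for name in BLOCK_NAMES for k in range(BLOCK_WIDTH)]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "gene", graph.symbols)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)
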