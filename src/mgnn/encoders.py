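"""Omics encoders: residual GCN layers, expression interaction bank, and
training-time graph/feature augmentation.

Each residual layer merges a node-wise linear path and a neighborhood
convolution path additively,

    H_linear = ReLU(H W_L),  H_conv = ReLU(S H W_c),  H' = H_linear + H_conv,

with S the normalized self-looped adjacency.  Each 16-dimensional omics
block gets its own two-layer encoder (widths 96 then 256); the expression
block additionally passes through three interaction encoders with
independent parameters, per-view MLPs, and a fusing linear map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import nn
from .graph_io import GeneGraph, normalized_operator
from .nn import Linear, LayerNorm, Module, Tensor, concat, spmm


@dataclass
class AugmentationConfig:
    """Random feature masking and edge dropping applied during training."""

    feature_mask_rate: float = 0.1
    edge_drop_rate: float = 0.1
    enabled: bool = True

    def __post_init__(self):
        for name in ("feature_mask_rate", "edge_drop_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")


class ResidualGCNLayer(Module):
    """Additive merge of a linear path and a convolution path."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.linear = Linear(d_in, d_out, rng, dtype=dtype)
        self.conv = Linear(d_in, d_out, rng, dtype=dtype)

    def __call__(self, H: Tensor, norm_adj: sp.spmatrix) -> Tensor:
        return self.linear(H).relu() + spmm(norm_adj, self.conv(H)).relu()


class GATLayer(Module):
    """Single-head graph attention layer (ablation encoder variant)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.proj = Linear(d_in, d_out, rng, bias=False, dtype=dtype)
        limit = np.sqrt(6.0 / (d_out + 1))
        self.a_src = nn.Parameter(rng.uniform(-limit, limit, (d_out, 1)).astype(dtype))
        self.a_dst = nn.Parameter(rng.uniform(-limit, limit, (d_out, 1)).astype(dtype))

    def __call__(self, H: Tensor, norm_adj: sp.spmatrix) -> Tensor:
        # attention runs over the self-looped edge set of the operator
        coo = sp.coo_matrix(norm_adj)
        src, dst = coo.col, coo.row
        h = self.proj(H)
        e = (nn.gather_rows(h @ self.a_src, src)
             + nn.gather_rows(h @ self.a_dst, dst)).leaky_relu(0.2)
        # per-destination softmax: exp / segment sum, max-shifted for stability
        shift = np.zeros(norm_adj.shape[0])
        np.maximum.at(shift, dst, e.data.ravel())
        e = (e - Tensor(shift[dst, None])).exp()
        denom = nn.segment_sum(e, dst, norm_adj.shape[0])
        w = e / nn.gather_rows(denom, dst)
        out = nn.segment_sum(w * nn.gather_rows(h, src), dst, norm_adj.shape[0])
        return out.relu()


class SAGELayer(Module):
    """Mean-aggregator GraphSAGE layer (shared-encoder ablation variant)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.self_map = Linear(d_in, d_out, rng, dtype=dtype)
        self.neigh_map = Linear(d_in, d_out, rng, bias=False, dtype=dtype)

    def __call__(self, H: Tensor, norm_adj: sp.spmatrix) -> Tensor:
        # row-normalize the operator into a mean aggregator
        A = sp.csr_matrix(norm_adj)
        rowsum = np.asarray(A.sum(axis=1)).ravel()
        rowsum[rowsum == 0] = 1.0
        A_mean = sp.diags(1.0 / rowsum) @ A
        return (self.self_map(H) + spmm(A_mean, self.neigh_map(H))).relu()


_LAYER_TYPES = {"residual_gcn": ResidualGCNLayer, "gat": GATLayer, "sage": SAGELayer}


class OmicsEncoder(Module):
    """Two-layer graph encoder for one 16-dim omics block, with a final
    layer normalization."""

    def __init__(self, d_in: int, rng: np.random.Generator, hidden1: int = 96,
                 hidden2: int = 256, layer_type: str = "residual_gcn",
                 dtype=np.float64):
        cls = _LAYER_TYPES[layer_type]
        self.d_in = d_in
        self.layers = [cls(d_in, hidden1, rng, dtype=dtype),
                       cls(hidden1, hidden2, rng, dtype=dtype)]
        self.norm = LayerNorm(hidden2, dtype=dtype)

    def __call__(self, block: Tensor, norm_adj: sp.spmatrix) -> Tensor:
        if block.shape[1] != self.d_in:
            raise ValueError(
                f"encoder expects width {self.d_in}, got {block.shape[1]}")
        H = block
        for layer in self.layers:
            H = layer(H, norm_adj)
        return self.norm(H)


class ViewMLP(Module):
    """One-hidden-layer MLP applied to a single expression view."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator, dtype=np.float64):
        self.fc1 = Linear(d_in, d_hidden, rng, dtype=dtype)
        self.fc2 = Linear(d_hidden, d_out, rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class ExpressionInteractionBank(Module):
    """Three interaction encoders + per-view MLPs + fusing linear map.

    The three views target expression-mutation, expression-methylation and
    expression-CNV interaction patterns; structure is shared, parameters are
    not.  By default each view consumes the expression block alone; with
    ``pair_input`` the paired omics block is concatenated to the input.
    """

    def __init__(self, rng: np.random.Generator, hidden1: int = 96,
                 hidden2: int = 256, layer_type: str = "residual_gcn",
                 pair_input: bool = False, block_width: int = 16,
                 dtype=np.float64):
        d_in = block_width * (2 if pair_input else 1)
        self.pair_input = pair_input
        self.view_encoders = [
            OmicsEncoder(d_in, rng, hidden1, hidden2, layer_type, dtype=dtype)
            for _ in range(3)
        ]
        self.view_mlps = [ViewMLP(hidden2, hidden2, hidden2, rng, dtype=dtype)
                          for _ in range(3)]
        self.fuse = Linear(3 * hidden2, hidden2, rng, dtype=dtype)

    def __call__(self, expr_block: Tensor, norm_adj: sp.spmatrix,
                 paired_blocks: tuple[Tensor, Tensor, Tensor] | None = None
                 ) -> Tensor:
        views = []
        for k, (enc, mlp) in enumerate(zip(self.view_encoders, self.view_mlps)):
            x = expr_block
            if self.pair_input:
                if paired_blocks is None:
                    raise ValueError("pair_input requires the paired omics blocks")
                x = concat([expr_block, paired_blocks[k]], axis=1)
            views.append(mlp(enc(x, norm_adj)))
        return self.fuse(concat(views, axis=1))


def encode_single_omics(encoder: OmicsEncoder, block: np.ndarray | Tensor,
                        norm_adj: sp.spmatrix) -> Tensor:
    return encoder(block if isinstance(block, Tensor) else Tensor(block), norm_adj)


def encode_expression(bank: ExpressionInteractionBank,
                      expr_block: np.ndarray | Tensor, norm_adj: sp.spmatrix,
                      paired_blocks=None) -> Tensor:
    x = expr_block if isinstance(expr_block, Tensor) else Tensor(expr_block)
    return bank(x, norm_adj, paired_blocks)


def augment(X: np.ndarray, graph: GeneGraph, cfg: AugmentationConfig,
            seed: int) -> tuple[np.ndarray, sp.csr_matrix]:
    """Feature masking + undirected edge dropping with re-normalization.

    Each feature entry is independently zeroed with ``feature_mask_rate``;
    each undirected edge is dropped (both directions) with
    ``edge_drop_rate``; the normalized operator is recomputed on the
    augmented graph.  Deterministic under ``seed``.
    """
    if not cfg.enabled:
        raise ValueError("augment called with augmentation disabled")
    rng = np.random.default_rng(seed)
    X_aug = np.array(X, copy=True)
    if cfg.feature_mask_rate > 0:
        X_aug[rng.random(X.shape) < cfg.feature_mask_rate] = 0.0
    edges = sorted(graph.edges)
    if cfg.edge_drop_rate > 0 and edges:
        keep = rng.random(len(edges)) >= cfg.edge_drop_rate
        edges = [e for e, k in zip(edges, keep) if k]
    n = graph.n_nodes
    if edges:
        rows, cols = zip(*edges)
        A = sp.coo_matrix((np.ones(len(edges)), (rows, cols)), shape=(n, n))
        A = (A + A.T).tocsr()
    else:
        A = sp.csr_matrix((n, n))
    return X_aug, normalized_operator(A)
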