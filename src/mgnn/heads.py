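"""Projection layer, deep residual-GCN classifier head, MLP head, and
additive logit fusion.

The enhanced representation is first projected (one residual GCN layer,
default width 128), then classified in parallel by a 6-layer residual GCN
head (dropout between layers) and a 3-layer MLP head (input layer-norm,
dropout before its output map).  The final logit is the exact sum of the
two head logits; probabilities come from a numerically stable sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .encoders import ResidualGCNLayer
from .nn import LayerNorm, Linear, Module, Tensor, dropout


@dataclass
class Prediction:
    logits: np.ndarray            # N
    probabilities: np.ndarray     # N
    head_logits: tuple[np.ndarray, np.ndarray]   # (gcn, mlp)
    logits_tensor: Tensor | None = None          # kept for backprop


class ProjectionLayer(Module):
    """Residual GCN layer mapping the hidden width to the head width."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64):
        self.layer = ResidualGCNLayer(d_in, d_out, rng, dtype=dtype)

    def __call__(self, H: Tensor, norm_adj: sp.spmatrix) -> Tensor:
        return self.layer(H, norm_adj)


class GCNHead(Module):
    """Deep residual GCN classifier: ReLU paths merged additively, then
    dropout, per layer; a final linear map emits one logit per node."""

    def __init__(self, d_in: int, rng: np.random.Generator,
                 widths: tuple[int, ...] = (200,) * 6, p_dropout: float = 0.2,
                 dtype=np.float64):
        dims = [d_in, *widths]
        self.layers = [ResidualGCNLayer(dims[i], dims[i + 1], rng, dtype=dtype)
                       for i in range(len(widths))]
        self.out = Linear(dims[-1], 1, rng, dtype=dtype)
        self.p_dropout = p_dropout

    def __call__(self, H: Tensor, norm_adj: sp.spmatrix, train: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        for layer in self.layers:
            H = dropout(layer(H, norm_adj), self.p_dropout, rng, train)
        return self.out(H)


class MLPHead(Module):
    """3-layer feed-forward head: layer-normalized input, two ReLU layers,
    dropout on the third transform, then a linear output map."""

    def __init__(self, d_in: int, rng: np.random.Generator,
                 widths: tuple[int, int, int] = (256, 128, 64),
                 p_dropout: float = 0.2, dtype=np.float64):
        w1, w2, w3 = widths
        self.in_norm = LayerNorm(d_in, dtype=dtype)
        self.fc1 = Linear(d_in, w1, rng, dtype=dtype)
        self.fc2 = Linear(w1, w2, rng, dtype=dtype)
        self.fc3 = Linear(w2, w3, rng, dtype=dtype)
        self.out = Linear(w3, 1, rng, dtype=dtype)
        self.p_dropout = p_dropout

    def __call__(self, H: Tensor, train: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = self.fc1(self.in_norm(H)).relu()
        h = self.fc2(h).relu()
        h = dropout(self.fc3(h), self.p_dropout, rng, train)
        return self.out(h)


class DualHead(Module):
    """Projection + parallel GCN/MLP heads with additive logit fusion."""

    def __init__(self, d_h: int, rng: np.random.Generator,
                 projection_dim: int = 128, gcn_widths: tuple[int, ...] = (200,) * 6,
                 mlp_widths: tuple[int, int, int] = (256, 128, 64),
                 p_dropout: float = 0.2, use_mlp_head: bool = True,
                 dtype=np.float64):
        self.projection = ProjectionLayer(d_h, projection_dim, rng, dtype=dtype)
        self.gcn_head = GCNHead(projection_dim, rng, gcn_widths, p_dropout,
                                dtype=dtype)
        self.mlp_head = (MLPHead(projection_dim, rng, mlp_widths, p_dropout,
                                 dtype=dtype) if use_mlp_head else None)

    def __call__(self, H_enhanced: Tensor, norm_adj: sp.spmatrix,
                 train: bool = False,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Tensor, Tensor, Tensor | None]:
        H_proj = self.projection(H_enhanced, norm_adj)
        y_gcn = self.gcn_head(H_proj, norm_adj, train, rng)
        if self.mlp_head is None:
            return y_gcn, y_gcn, None
        y_mlp = self.mlp_head(H_proj, train, rng)
        return y_gcn + y_mlp, y_gcn, y_mlp


def forward_heads(H_enhanced: Tensor, norm_adj: sp.spmatrix, heads: DualHead,
                  eval_mode: bool = True,
                  rng: np.random.Generator | None = None) -> Prediction:
    y, y_gcn, y_mlp = heads(H_enhanced, norm_adj, train=not eval_mode, rng=rng)
    logits = y.data.ravel().copy()
    mlp_logits = (y_mlp.data.ravel().copy() if y_mlp is not None
                  else np.zeros_like(logits))
    return Prediction(
        logits=logits,
        probabilities=sigmoid_probability(logits),
        head_logits=(y_gcn.data.ravel().copy(), mlp_logits),
        logits_tensor=y,
    )


def sigmoid_probability(logits: np.ndarray) -> np.ndarray:
    """Elementwise 1/(1+exp(-x)), overflow-free for large |x|."""
    x = np.asarray(logits, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
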