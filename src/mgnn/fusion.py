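"""Per-node additive attention over omics embeddings and weighted fusion.

For node i with omics embeddings s_i^(m), m = 1..k, the score of omics m is
``v^T sigma(W_a s_i^(m) + b_a)``; a softmax over m yields scalar weights
a_i^(m) that sum to one, and the fused row is ``sum_m a_i^(m) * s_i^(m)``.
The ablation variant replaces attention by a plain elementwise sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor, concat


@dataclass
class FusedRepresentation:
    values: Tensor            # N x d_h
    attention_weights: np.ndarray  # N x k diagnostic weight matrix


class AttentionFuser(Module):
    """Single-head additive attention across omics embeddings."""

    def __init__(self, d_h: int, d_a: int = 64, rng: np.random.Generator | None = None,
                 activation: str = "tanh", dtype=np.float64):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.score_map = Linear(d_h, d_a, rng, dtype=dtype)   # W_a, b_a
        self.v = Linear(d_a, 1, rng, bias=False, dtype=dtype)
        if activation not in ("tanh", "relu"):
            raise ValueError(f"unknown attention activation {activation!r}")
        self.activation = activation

    def scores(self, embeddings: list[Tensor]) -> Tensor:
        cols = []
        for H in embeddings:
            z = self.score_map(H)
            z = z.tanh() if self.activation == "tanh" else z.relu()
            cols.append(self.v(z))          # N x 1
        return concat(cols, axis=1)         # N x k


def attend(fuser: AttentionFuser, embeddings: list[Tensor]) -> FusedRepresentation:
    shapes = {H.shape for H in embeddings}
    if len(shapes) != 1:
        raise ValueError(f"omics embeddings disagree in shape: {shapes}")
    weights = fuser.scores(embeddings).softmax(axis=1)     # N x k
    fused = None
    for m, H in enumerate(embeddings):
        term = weights[:, m : m + 1] * H
        fused = term if fused is None else fused + term
    return FusedRepresentation(values=fused, attention_weights=weights.data.copy())


def fuse_without_attention(embeddings: list[Tensor]) -> FusedRepresentation:
    """Ablation: plain sum; diagnostic weights are all ones (unnormalized)."""
    shapes = {H.shape for H in embeddings}
    if len(shapes) != 1:
        raise ValueError(f"omics embeddings disagree in shape: {shapes}")
    fused = embeddings[0]
    for H in embeddings[1:]:
        fused = fused + H
    n = embeddings[0].shape[0]
    return FusedRepresentation(values=fused,
                               attention_weights=np.ones((n, len(embeddings))))
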