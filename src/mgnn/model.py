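"""The assembled multi-modal GNN: omics encoders -> attention fusion ->
residual feature enhancement -> dual prediction heads."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .config import ALL_BLOCKS, ModelConfig
from .encoders import ExpressionInteractionBank, OmicsEncoder
from .enhancement import ExtraMLP, enhance
from .fusion import AttentionFuser, FusedRepresentation, attend, fuse_without_attention
from .graph_io import BLOCK_WIDTH, OmicsMatrix
from .heads import DualHead, Prediction, forward_heads
from .nn import Module, Tensor


class MGNN(Module):
    """Student/teacher network over a fixed gene graph.

    ``n_extra`` is the width of the concatenated enhancement features
    (0 disables the enhancement MLP).  The teacher variant differs only in
    classifier widths and dropout, passed through ``head_overrides``.
    """

    def __init__(self, cfg: ModelConfig, n_extra: int, rng: np.random.Generator,
                 gcn_widths: tuple[int, ...] | None = None,
                 dropout: float | None = None, dtype=np.float32):
        enc, d_h = cfg.encoder, cfg.encoder.hidden2
        self.cfg = cfg
        self.dtype = dtype
        self.blocks = tuple(cfg.blocks)
        self.shared = enc.shared
        if self.shared:
            self.shared_encoder = OmicsEncoder(
                BLOCK_WIDTH * len(self.blocks), rng, enc.hidden1, d_h,
                layer_type=enc.type if enc.type != "residual_gcn" else "sage",
                dtype=dtype)
        else:
            self.single_encoders = {
                b: OmicsEncoder(BLOCK_WIDTH, rng, enc.hidden1, d_h, enc.type,
                                dtype=dtype)
                for b in self.blocks if b != "expression"
            }
            self.expression_bank = (
                ExpressionInteractionBank(rng, enc.hidden1, d_h, enc.type,
                                          pair_input=enc.expression_pair_input,
                                          dtype=dtype)
                if "expression" in self.blocks else None)
        self.fuser = (AttentionFuser(d_h, cfg.fusion.d_a, rng,
                                     cfg.fusion.activation, dtype=dtype)
                      if cfg.fusion.attention else None)
        self.mlp_extra = (ExtraMLP(n_extra, d_h, rng, dtype=dtype)
                          if n_extra > 0 else None)
        p_drop = cfg.train.dropout if dropout is None else dropout
        widths = gcn_widths or (cfg.heads.gcn_width,) * cfg.heads.gcn_depth
        self.head = DualHead(d_h, rng, cfg.heads.projection_dim, widths,
                             cfg.heads.mlp_widths, p_drop,
                             cfg.heads.use_mlp_head, dtype=dtype)
        self.last_attention: np.ndarray | None = None

    # named_parameters skips dict attributes; expose encoders as a list too
    def named_parameters(self, prefix: str = ""):
        out = []
        if self.shared:
            out += self.shared_encoder.named_parameters(prefix + "shared_encoder.")
        else:
            for b, enc in self.single_encoders.items():
                out += enc.named_parameters(f"{prefix}encoder.{b}.")
            if self.expression_bank is not None:
                out += self.expression_bank.named_parameters(prefix + "expression.")
        if self.fuser is not None:
            out += self.fuser.named_parameters(prefix + "fuser.")
        if self.mlp_extra is not None:
            out += self.mlp_extra.named_parameters(prefix + "mlp_extra.")
        out += self.head.named_parameters(prefix + "head.")
        return out

    def embed(self, omics: OmicsMatrix, norm_adj: sp.spmatrix) -> FusedRepresentation:
        norm_adj = norm_adj.astype(self.dtype)
        X = Tensor(omics.values.astype(self.dtype, copy=False))
        slices = omics.block_slices
        if self.shared:
            cols = np.concatenate([np.arange(s.start, s.stop)
                                   for b, s in slices.items() if b in self.blocks])
            H = self.shared_encoder(X[:, cols], norm_adj)
            n = omics.values.shape[0]
            return FusedRepresentation(values=H,
                                       attention_weights=np.ones((n, 1)))
        embeddings = []
        paired_names = [b for b in ("mutation", "methylation", "cnv")]
        for b in ALL_BLOCKS:
            if b not in self.blocks:
                continue
            if b == "expression":
                paired = tuple(X[:, slices[p]] for p in paired_names)
                embeddings.append(self.expression_bank(
                    X[:, slices[b]], norm_adj,
                    paired if self.expression_bank.pair_input else None))
            else:
                embeddings.append(self.single_encoders[b](X[:, slices[b]], norm_adj))
        if len(embeddings) == 1:
            n = omics.values.shape[0]
            return FusedRepresentation(values=embeddings[0],
                                       attention_weights=np.ones((n, 1)))
        if self.fuser is not None:
            fused = attend(self.fuser, embeddings)
        else:
            fused = fuse_without_attention(embeddings)
        return fused

    def forward(self, omics: OmicsMatrix, norm_adj: sp.spmatrix,
                x_extra: np.ndarray | None, train: bool = False,
                rng: np.random.Generator | None = None) -> Prediction:
        fused = self.embed(omics, norm_adj)
        self.last_attention = fused.attention_weights
        if x_extra is not None:
            x_extra = np.asarray(x_extra).astype(self.dtype, copy=False)
        H_enh = enhance(fused.values, x_extra, self.mlp_extra)
        return forward_heads(H_enh, norm_adj.astype(self.dtype), self.head,
                             eval_mode=not train, rng=rng)

    def zero_convolution_paths(self) -> None:
        """Zero every convolution-path weight; predictions become
        independent of graph topology (diagnostic reduction)."""
        for name, p in self.named_parameters():
            if ".conv." in name:
                p.data[...] = 0.0
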