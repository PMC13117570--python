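"""Teacher ensemble training and soft-label production.

Teachers share the student's multi-encoder architecture but with
higher-capacity classifier layers; they are trained with class-balanced
BCE only (no distillation), early-stopped on validation AUPRC, and their
parameter EMA provides the final logits.  The ensemble's per-node mean
logit is the soft label consumed by student runs, both as an input feature
and as the distillation target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .enhancement import EnhancementBundle
from .graph_io import GeneGraph, LabelSet, OmicsMatrix, fit_standardizer, standardize_array
from .model import MGNN
from .objectives import LossConfig
from .training import fit_model, predict_logits, stratified_val_split


@dataclass
class SoftLabels:
    logits: np.ndarray                       # N
    per_teacher_logits: np.ndarray | None    # N x n_teachers
    provenance: dict

    def __post_init__(self):
        if not np.all(np.isfinite(self.logits)):
            raise ValueError("soft labels must be finite")


def _teacher_bundle(bundle: EnhancementBundle | None) -> EnhancementBundle | None:
    """Teachers consume structural/walk extras but never teacher logits."""
    if bundle is None:
        return None
    toggles = dict(bundle.toggles)
    toggles["teacher"] = False
    return EnhancementBundle(structural=bundle.structural, walks=bundle.walks,
                             teacher_logits=None, toggles=toggles)


def train_teacher(graph: GeneGraph, omics: OmicsMatrix, labels: LabelSet,
                  cfg: ModelConfig, train_idx: np.ndarray, seed: int,
                  bundle: EnhancementBundle | None = None,
                  epochs: int | None = None) -> np.ndarray:
    """Train one teacher on the training-fold labels; returns logits for
    ALL nodes.  ``omics`` must already be standardized with train-fold
    statistics.  A 10% stratified validation subset of the training labels
    drives early stopping; the loss sees only the remaining 90%.
    """
    tc = cfg.teacher
    train_idx = np.asarray(train_idx)
    y_all = labels.y(train_idx)
    fit_idx, val_idx = stratified_val_split(train_idx, y_all,
                                            tc.val_fraction, seed)
    y_fit = labels.y(fit_idx)
    y_val = labels.y(val_idx)

    x_extra = None
    tb = _teacher_bundle(bundle)
    if tb is not None:
        raw = tb.x_extra()
        if raw is not None:
            stats = fit_standardizer(raw, train_idx)
            x_extra = standardize_array(raw, stats)

    rng = np.random.default_rng(seed)
    model = MGNN(cfg, n_extra=0 if x_extra is None else x_extra.shape[1],
                 rng=rng, gcn_widths=tc.classifier_widths, dropout=tc.dropout)
    fit_model(
        model, graph, omics, x_extra, y_fit, fit_idx,
        lr=tc.lr, weight_decay=tc.weight_decay,
        epochs=epochs if epochs is not None else tc.epochs,
        loss_cfg=LossConfig(lambda_kd=0.0, class_weights="auto"),
        augment_cfg=cfg.augment,
        val_idx=val_idx, val_y=y_val, patience=tc.patience,
        ema_decay=tc.ema_decay, seed=int(rng.integers(2**31)),
    )
    return predict_logits(model, omics, graph.norm_adjacency, x_extra)


def ensemble_soft_labels(per_teacher: list[np.ndarray],
                         provenance: dict | None = None) -> SoftLabels:
    """Arithmetic mean of per-teacher logits, node by node."""
    if not per_teacher:
        raise ValueError("need at least one teacher")
    mat = np.stack([np.asarray(t).ravel() for t in per_teacher], axis=1)
    if len({t.shape for t in [np.asarray(t).ravel() for t in per_teacher]}) != 1:
        raise ValueError("teacher logit vectors disagree in shape")
    return SoftLabels(logits=mat.mean(axis=1), per_teacher_logits=mat,
                      provenance=provenance or {})


def train_teacher_ensemble(graph: GeneGraph, omics: OmicsMatrix,
                           labels: LabelSet, cfg: ModelConfig,
                           train_idx: np.ndarray, seed: int,
                           bundle: EnhancementBundle | None = None,
                           n_teachers: int | None = None,
                           epochs: int | None = None) -> SoftLabels:
    n = cfg.teacher.n_teachers if n_teachers is None else n_teachers
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n)]
    per = [train_teacher(graph, omics, labels, cfg, train_idx, s,
                         bundle=bundle, epochs=epochs) for s in seeds]
    return ensemble_soft_labels(
        per, provenance={"seeds": seeds,
                         "train_rows": sorted(int(i) for i in train_idx)})


def write_soft_labels(soft: SoftLabels, graph: GeneGraph, path) -> None:
    path = Path(path)
    pd.DataFrame({"gene": graph.symbols, "logit": soft.logits}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(soft.provenance, fh, indent=1)
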