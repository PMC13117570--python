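"""Full-batch training loop shared by teacher and student models.

Each epoch: augment features/edges (training only), forward with dropout,
class-balanced task loss on the labeled training nodes plus the optional
distillation term, AdamW step, optional parameter EMA, optional early
stopping on validation AUPRC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoders import AugmentationConfig, augment
from .graph_io import GeneGraph, OmicsMatrix
from .metrics import compute_metrics
from .model import MGNN
from .nn import EMA, AdamW
from .objectives import (
    LossConfig,
    auto_class_weights,
    balanced_bce,
    focal_loss,
    kd_loss,
    total_loss,
)


class DivergenceError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass
class FitResult:
    history: list[dict] = field(default_factory=list)
    best_val_auprc: float | None = None
    stopped_epoch: int | None = None


def predict_logits(model: MGNN, omics: OmicsMatrix, norm_adj,
                   x_extra: np.ndarray | None) -> np.ndarray:
    """Deterministic evaluation-mode logits for all nodes."""
    return model.forward(omics, norm_adj, x_extra, train=False).logits


def fit_model(model: MGNN, graph: GeneGraph, omics: OmicsMatrix,
              x_extra: np.ndarray | None, y_task: np.ndarray,
              task_idx: np.ndarray, *, lr: float, weight_decay: float,
              epochs: int, loss_cfg: LossConfig,
              augment_cfg: AugmentationConfig | None = None,
              kd_logits: np.ndarray | None = None,
              kd_idx: np.ndarray | None = None,
              val_idx: np.ndarray | None = None,
              val_y: np.ndarray | None = None,
              patience: int | None = None, ema_decay: float | None = None,
              eval_every: int = 10, seed: int = 0) -> FitResult:
    """Train ``model`` in place; returns the loss/validation history.

    ``y_task``/``task_idx`` define the supervised term; ``kd_logits`` (full
    N-vector) with ``kd_idx`` add the distillation term weighted by
    ``loss_cfg.lambda_kd``.  With ``val_idx``/``patience`` the loop stops
    once validation AUPRC has not improved for ``patience`` epochs, and the
    best parameters (EMA parameters when ``ema_decay`` is set) are restored.
    """
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(int(rng.integers(2**31)))
    aug_seeds = np.random.default_rng(int(rng.integers(2**31)))
    opt = AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    ema = EMA(model.parameters(), ema_decay) if ema_decay is not None else None

    if loss_cfg.class_weights == "auto":
        weights = auto_class_weights(y_task)
    else:
        weights = tuple(loss_cfg.class_weights)

    use_kd = (kd_logits is not None and loss_cfg.lambda_kd > 0
              and kd_idx is not None and len(kd_idx) > 0)
    result = FitResult()
    best_val = -np.inf
    best_state: list[np.ndarray] | None = None
    since_best = 0
    norm_adj = graph.norm_adjacency

    for epoch in range(epochs):
        if augment_cfg is not None and augment_cfg.enabled and (
                augment_cfg.feature_mask_rate > 0 or augment_cfg.edge_drop_rate > 0):
            X_aug, S_aug = augment(omics.values, graph, augment_cfg,
                                   seed=int(aug_seeds.integers(2**31)))
            om = OmicsMatrix(X_aug, standardized=omics.standardized)
        else:
            om, S_aug = omics, norm_adj
        pred = model.forward(om, S_aug, x_extra, train=True, rng=drop_rng)
        z = pred.logits_tensor.reshape(-1)
        if loss_cfg.use_focal:
            task = focal_loss(z[task_idx], y_task, loss_cfg.focal_gamma, weights)
        else:
            task = balanced_bce(z[task_idx], y_task, weights)
        if use_kd:
            kd = kd_loss(z[kd_idx], kd_logits[kd_idx])
            loss = task + loss_cfg.lambda_kd * kd
        else:
            kd = None
            loss = task
        if not np.isfinite(loss.data):
            raise DivergenceError(
                f"non-finite loss at epoch {epoch}: task={task.data}")
        model.zero_grad()
        loss.backward()
        opt.step()
        if ema is not None:
            ema.update()
        report = total_loss(task, kd if kd is not None else 0.0,
                            loss_cfg.lambda_kd if use_kd else 0.0)
        entry = {"epoch": epoch, "task_loss": report.task_loss,
                 "kd_loss": report.kd_loss, "total_loss": report.total}

        if val_idx is not None and (epoch + 1) % eval_every == 0:
            stash = ema.swap() if ema is not None else None
            logits = predict_logits(model, omics, norm_adj, x_extra)
            if stash is not None:
                for p, a in zip(model.parameters(), stash):
                    p.data = a
            _, val_auprc = compute_metrics(logits[val_idx], val_y)
            entry["val_auprc"] = val_auprc
            if val_auprc > best_val:
                best_val = val_auprc
                best_state = ([np.array(s, copy=True) for s in ema.shadow]
                              if ema is not None else
                              [np.array(p.data, copy=True)
                               for p in model.parameters()])
                since_best = 0
            else:
                since_best += eval_every
            result.history.append(entry)
            if patience is not None and since_best >= patience:
                result.stopped_epoch = epoch
                break
        else:
            result.history.append(entry)

    if val_idx is not None and best_state is not None:
        model.load_state_arrays(best_state)
        result.best_val_auprc = float(best_val)
    elif ema is not None:
        ema.copy_to()
    return result


def stratified_val_split(labeled_idx: np.ndarray, y: np.ndarray,
                         val_fraction: float, seed: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Carve a stratified validation subset out of the labeled training
    nodes (used for early stopping and ensemble weighting only)."""
    rng = np.random.default_rng(seed)
    labeled_idx = np.asarray(labeled_idx)
    y = np.asarray(y)
    val_mask = np.zeros(len(labeled_idx), dtype=bool)
    for cls in (0, 1):
        cls_pos = np.where(y == cls)[0]
        n_val = max(1, int(round(val_fraction * len(cls_pos))))
        val_mask[rng.choice(cls_pos, size=n_val, replace=False)] = True
    return labeled_idx[~val_mask], labeled_idx[val_mask]
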