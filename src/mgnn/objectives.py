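"""Training objectives: class-balanced BCE, optional focal loss, soft-label
distillation loss, and the combined total.

All losses are computed from logits via stable log-sigmoid identities
(``-log sigma(z) = softplus(-z)``), so they are finite for logits far into
the hundreds.  The combined objective is ``L = L_B + lambda * L_K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor


@dataclass
class LossConfig:
    lambda_kd: float = 0.5
    class_weights: tuple[float, float] | str = "auto"   # (w_p, w_n) or "auto"
    use_focal: bool = False
    focal_gamma: float = 2.0
    distill_include_unlabeled: bool = True
    scope: str = "labeled"   # the task loss averages over labeled train nodes


@dataclass
class LossReport:
    task_loss: float
    kd_loss: float
    lambda_kd: float
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.task_loss + self.lambda_kd * self.kd_loss


def auto_class_weights(labels: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency, mean-preserving weights: w_p*N_pos = w_n*N_neg = N/2."""
    y = np.asarray(labels)
    n, n_pos = len(y), int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auto class weights need both classes present")
    return n / (2.0 * n_pos), n / (2.0 * n_neg)


def _as_t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def balanced_bce(logits, labels: np.ndarray,
                 weights: tuple[float, float] = (1.0, 1.0)) -> Tensor:
    """-(1/N) sum [w_p y log sigma(z) + w_n (1-y) log(1 - sigma(z))]."""
    z = _as_t(logits)
    y = np.asarray(labels, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("balanced_bce needs at least one sample")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be 0/1")
    z = z.reshape(-1)
    w_p, w_n = weights
    y_t = Tensor(y)
    # -log sigma(z) = softplus(-z);  -log(1-sigma(z)) = softplus(z)
    per = y_t * (w_p * (-z).softplus()) + (1.0 - y_t) * (w_n * z.softplus())
    return per.mean()


def focal_loss(logits, labels: np.ndarray, gamma: float = 2.0,
               weights: tuple[float, float] = (1.0, 1.0)) -> Tensor:
    """-(1/N) sum w_class (1 - p_t)^gamma log p_t; gamma=0 is balanced BCE."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    z = _as_t(logits).reshape(-1)
    y = np.asarray(labels, dtype=float).ravel()
    w_p, w_n = weights
    y_t = Tensor(y)
    log_p = -(-z).softplus()       # log sigma(z)
    log_1mp = -z.softplus()        # log(1 - sigma(z))
    log_pt = y_t * log_p + (1.0 - y_t) * log_1mp
    w = Tensor(np.where(y == 1, w_p, w_n))
    if gamma == 0:
        per = w * (-log_pt)
    else:
        one_m_pt = 1.0 - log_pt.exp()
        per = w * one_m_pt.pow(gamma) * (-log_pt)
    return per.mean()


def kd_loss(student_logits, teacher_logits: np.ndarray,
            temperature: float = 1.0) -> Tensor:
    """Soft-target cross-entropy: teacher probabilities supervise the
    student's sigmoid; minimized when the two probabilities match."""
    zs = _as_t(student_logits).reshape(-1)
    zt = np.asarray(teacher_logits, dtype=float).ravel() / temperature
    if zt.size == 0:
        raise ValueError("distillation node set is empty")
    pt = _stable_sigmoid(zt)
    pt_t = Tensor(pt)
    per = pt_t * (-zs).softplus() + (1.0 - pt_t) * zs.softplus()
    return per.mean()


def total_loss(task, kd, lambda_kd: float) -> LossReport:
    if lambda_kd < 0:
        raise ValueError("lambda_kd must be >= 0")
    t = float(task.data) if isinstance(task, Tensor) else float(task)
    k = float(kd.data) if isinstance(kd, Tensor) else float(kd)
    return LossReport(task_loss=t, kd_loss=k, lambda_kd=lambda_kd)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
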