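"""Student training, repeated stratified cross-validation, ensembling,
negative-sampling experiments and the ablation harness.

The evaluation protocol is repeated stratified k-fold cross-validation
over the labeled nodes (default 10 repeats x 5 folds).  Within every fold,
feature standardization is fitted on training rows only, teachers are
retrained on the training fold (leak-free default), and test labels are
never touched before scoring.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import ModelConfig
from .distillation import SoftLabels, train_teacher_ensemble
from .enhancement import EnhancementBundle
from .graph_io import (
    GeneGraph,
    LabelSet,
    OmicsMatrix,
    apply_standardizer,
    fit_standardizer,
    standardize_array,
)
from .metrics import compute_metrics
from .model import MGNN
from .training import fit_model, predict_logits, stratified_val_split

__all__ = [
    "FoldPlan",
    "MetricReport",
    "compute_metrics",
    "cross_validate",
    "ensemble_students",
    "train_student",
    "negative_sampling_experiment",
    "run_ablation",
    "ABLATION_REGISTRY",
]


@dataclass
class Fold:
    repeat: int
    fold: int
    train_idx: np.ndarray     # global node indices (labeled)
    test_idx: np.ndarray


@dataclass
class FoldPlan:
    n_repeats: int
    n_folds: int
    folds: list[Fold]

    @classmethod
    def build(cls, labels: LabelSet, n_repeats: int = 10, n_folds: int = 5,
              seed: int = 0) -> "FoldPlan":
        labeled = labels.labeled
        y = labels.y(labeled)
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("labels are degenerate: both classes required")
        repeat_seeds = [int(s.generate_state(1)[0] % 2**31)
                        for s in np.random.SeedSequence(seed).spawn(n_repeats)]
        folds = []
        for r, rs in enumerate(repeat_seeds):
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
            for f, (tr, te) in enumerate(skf.split(labeled, y)):
                if y[te].sum() == 0:
                    raise ValueError(f"fold {r}/{f} has no positives")
                folds.append(Fold(repeat=r, fold=f, train_idx=labeled[tr],
                                  test_idx=labeled[te]))
        return cls(n_repeats=n_repeats, n_folds=n_folds, folds=folds)


@dataclass
class MetricReport:
    per_fold_auroc: list[float] = field(default_factory=list)
    per_fold_auprc: list[float] = field(default_factory=list)
    diagnostics: list[dict] = field(default_factory=list)

    @property
    def auroc_mean(self) -> float:
        return float(np.mean(self.per_fold_auroc))

    @property
    def auroc_std(self) -> float:
        return float(np.std(self.per_fold_auroc))

    @property
    def auprc_mean(self) -> float:
        return float(np.mean(self.per_fold_auprc))

    @property
    def auprc_std(self) -> float:
        return float(np.std(self.per_fold_auprc))


def ensemble_students(member_logits: list[np.ndarray],
                      val_scores: list[float] | None,
                      temperature: float = 0.08,
                      mode: str = "softmax") -> tuple[np.ndarray, np.ndarray]:
    """Combine member logits; softmax mode weighs members by
    softmax(validation AUPRC / T), plain-mean mode averages uniformly."""
    if not member_logits:
        raise ValueError("need at least one student")
    mat = np.stack([np.asarray(m).ravel() for m in member_logits], axis=1)
    k = mat.shape[1]
    if mode == "mean" or val_scores is None or k == 1:
        w = np.full(k, 1.0 / k)
    elif mode == "softmax":
        s = np.asarray(val_scores, dtype=float) / temperature
        s = s - s.max()
        w = np.exp(s)
        w /= w.sum()
    else:
        raise ValueError(f"unknown ensemble mode {mode!r}")
    return mat @ w, w


def train_student(graph: GeneGraph, omics_std: OmicsMatrix,
                  x_extra: np.ndarray | None, labels: LabelSet,
                  soft: SoftLabels | None, cfg: ModelConfig,
                  train_idx: np.ndarray, seed: int,
                  epochs: int | None = None) -> tuple[MGNN, dict]:
    """Train one student on (already standardized) inputs; returns the
    model and a small diagnostics record."""
    train_idx = np.asarray(train_idx)
    y = labels.y(train_idx)
    kd_logits = soft.logits if soft is not None else None
    if cfg.loss.distill_include_unlabeled:
        kd_idx = np.array(sorted(set(train_idx.tolist())
                                 | labels.unlabeled), dtype=int)
    else:
        kd_idx = train_idx
    rng = np.random.default_rng(seed)
    model = MGNN(cfg, n_extra=0 if x_extra is None else x_extra.shape[1], rng=rng)
    result = fit_model(
        model, graph, omics_std, x_extra, y, train_idx,
        lr=cfg.train.lr, weight_decay=cfg.train.weight_decay,
        epochs=epochs if epochs is not None else cfg.train.epochs,
        loss_cfg=cfg.loss, augment_cfg=cfg.augment,
        kd_logits=kd_logits, kd_idx=kd_idx,
        seed=int(rng.integers(2**31)),
    )
    return model, {"history": result.history}


def _fold_inputs(graph: GeneGraph, omics: OmicsMatrix, labels: LabelSet,
                 bundle: EnhancementBundle | None, cfg: ModelConfig,
                 train_idx: np.ndarray, seed: int,
                 teacher_epochs: int | None = None):
    """Standardize per fold and (re)train fold teachers; returns
    (omics_std, x_extra_std, soft_labels, diagnostics)."""
    stats = fit_standardizer(omics, train_idx)
    omics_std = apply_standardizer(omics, stats)
    diag = {"standardizer_rows": stats.source_rows}

    needs_teacher = (cfg.enhancement.teacher or cfg.loss.lambda_kd > 0)
    soft = None
    if needs_teacher and bundle is not None:
        soft = train_teacher_ensemble(graph, omics_std, labels, cfg, train_idx,
                                      seed=seed, bundle=bundle,
                                      epochs=teacher_epochs)
        diag["teacher_label_rows"] = frozenset(soft.provenance["train_rows"])

    x_extra = None
    if bundle is not None:
        fold_bundle = EnhancementBundle(
            structural=bundle.structural, walks=bundle.walks,
            teacher_logits=(soft.logits if soft is not None
                            and cfg.enhancement.teacher else None),
            toggles={"structural": cfg.enhancement.structural,
                     "walks": cfg.enhancement.walks,
                     "teacher": cfg.enhancement.teacher})
        raw = fold_bundle.x_extra()
        if raw is not None:
            extra_stats = fit_standardizer(raw, train_idx)
            x_extra = standardize_array(raw, extra_stats)
            diag["extra_standardizer_rows"] = extra_stats.source_rows
    return omics_std, x_extra, soft, diag


def _fit_fold(graph, omics, labels, bundle, cfg, train_idx, test_idx, seed,
              student_epochs=None, teacher_epochs=None):
    omics_std, x_extra, soft, diag = _fold_inputs(
        graph, omics, labels, bundle, cfg, train_idx, seed,
        teacher_epochs=teacher_epochs)
    n_members = cfg.train.n_student_ensemble
    member_seeds = [int(s.generate_state(1)[0] % 2**31)
                    for s in np.random.SeedSequence(seed + 1).spawn(n_members)]
    member_logits, val_scores = [], []
    if n_members > 1:
        fit_idx, val_idx = stratified_val_split(
            np.asarray(train_idx), labels.y(np.asarray(train_idx)),
            cfg.train.val_fraction, seed)
    else:
        fit_idx, val_idx = np.asarray(train_idx), None
    for ms in member_seeds:
        model, _ = train_student(graph, omics_std, x_extra, labels, soft, cfg,
                                 fit_idx, seed=ms, epochs=student_epochs)
        logits = predict_logits(model, omics_std, graph.norm_adjacency, x_extra)
        member_logits.append(logits)
        if val_idx is not None:
            _, vp = compute_metrics(logits[val_idx], labels.y(val_idx))
            val_scores.append(vp)
    combined, _ = ensemble_students(
        member_logits, val_scores if val_scores else None,
        cfg.train.ensemble_temperature, cfg.train.ensemble_mode)
    diag["train_idx"] = frozenset(int(i) for i in np.asarray(train_idx))
    return combined, diag


def cross_validate(graph: GeneGraph, omics: OmicsMatrix, labels: LabelSet,
                   bundle: EnhancementBundle | None, cfg: ModelConfig,
                   plan: FoldPlan, student_epochs: int | None = None,
                   teacher_epochs: int | None = None) -> MetricReport:
    """Per fold: standardize on train, retrain teachers on train, train
    student(s), score AUROC/AUPRC on the held-out fold."""
    report = MetricReport()
    base_seed = cfg.train.seed
    for k, fold in enumerate(plan.folds):
        scores, diag = _fit_fold(
            graph, omics, labels, bundle, cfg, fold.train_idx, fold.test_idx,
            seed=base_seed + 104729 * (k + 1),
            student_epochs=student_epochs, teacher_epochs=teacher_epochs)
        auroc, auprc = compute_metrics(scores[fold.test_idx],
                                       labels.y(fold.test_idx))
        report.per_fold_auroc.append(auroc)
        report.per_fold_auprc.append(auprc)
        diag["repeat"], diag["fold"] = fold.repeat, fold.fold
        diag["test_idx"] = frozenset(int(i) for i in fold.test_idx)
        report.diagnostics.append(diag)
    return report


def holdout_evaluate(graph: GeneGraph, omics: OmicsMatrix, labels: LabelSet,
                     bundle: EnhancementBundle | None, cfg: ModelConfig,
                     test_fraction: float = 0.25, seed: int = 0,
                     student_epochs: int | None = None,
                     teacher_epochs: int | None = None
                     ) -> tuple[float, float, dict]:
    """Single stratified train/test split (default 75%/25%)."""
    labeled = labels.labeled
    y = labels.y(labeled)
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(labeled), dtype=bool)
    for cls in (0, 1):
        pos = np.where(y == cls)[0]
        n_test = max(1, int(round(test_fraction * len(pos))))
        test_mask[rng.choice(pos, size=n_test, replace=False)] = True
    train_idx, test_idx = labeled[~test_mask], labeled[test_mask]
    scores, diag = _fit_fold(graph, omics, labels, bundle, cfg, train_idx,
                             test_idx, seed=seed,
                             student_epochs=student_epochs,
                             teacher_epochs=teacher_epochs)
    auroc, auprc = compute_metrics(scores[test_idx], labels.y(test_idx))
    diag["test_idx"] = frozenset(int(i) for i in test_idx)
    return auroc, auprc, diag


def subsample_negatives(train_idx: np.ndarray, labels: LabelSet, ratio,
                        rng: np.random.Generator) -> np.ndarray:
    """Keep all training positives and ``ratio`` times as many negatives
    (``"all"`` keeps everything); clamps with a warning when the ratio
    exceeds the available negatives."""
    train_idx = np.asarray(train_idx)
    if ratio == "all":
        return train_idx
    y = labels.y(train_idx)
    pos = train_idx[y == 1]
    neg = train_idx[y == 0]
    n_keep = int(round(float(ratio) * len(pos)))
    if n_keep > len(neg):
        import warnings
        warnings.warn(f"ratio {ratio} exceeds available negatives; keeping all")
        n_keep = len(neg)
    keep = rng.choice(neg, size=n_keep, replace=False)
    return np.sort(np.concatenate([pos, keep]))


def negative_sampling_experiment(graph, omics, labels, bundle, cfg,
                                 plan: FoldPlan, ratios: list,
                                 seed: int = 0, student_epochs=None,
                                 teacher_epochs=None) -> dict:
    """Subsample training negatives to the given negative:positive ratios
    (``"all"`` keeps them all); test folds are untouched."""
    out = {}
    rng = np.random.default_rng(seed)
    for ratio in ratios:
        report = MetricReport()
        for k, fold in enumerate(plan.folds):
            train_idx = subsample_negatives(fold.train_idx, labels, ratio, rng)
            scores, _ = _fit_fold(graph, omics, labels, bundle, cfg, train_idx,
                                  fold.test_idx,
                                  seed=cfg.train.seed + 104729 * (k + 1),
                                  student_epochs=student_epochs,
                                  teacher_epochs=teacher_epochs)
            auroc, auprc = compute_metrics(scores[fold.test_idx],
                                           labels.y(fold.test_idx))
            report.per_fold_auroc.append(auroc)
            report.per_fold_auprc.append(auprc)
        out[str(ratio)] = report
    return out


# -- ablation registry -----------------------------------------------------


def _with(cfg: ModelConfig, **updates) -> ModelConfig:
    new = dataclasses.replace(cfg)
    for dotted, value in updates.items():
        parts = dotted.split("__")
        obj = new
        for p in parts[:-1]:
            setattr(obj, p, dataclasses.replace(getattr(obj, p)))
            obj = getattr(obj, p)
        setattr(obj, parts[-1], value)
    return new


ABLATION_REGISTRY: dict[str, callable] = {
    "XM+XT": lambda c: _with(c, blocks=("mutation", "methylation")),
    "XM+XE+XT": lambda c: _with(c, blocks=("mutation", "expression", "methylation")),
    "XM+XE+XC": lambda c: _with(c, blocks=("mutation", "expression", "cnv")),
    "XE+XT+XC": lambda c: _with(c, blocks=("expression", "methylation", "cnv")),
    "XM+XE+XT+XC": lambda c: c,
    "without_independent_encoding": lambda c: _with(c, encoder__shared=True),
    "independent_encoding_by_gat": lambda c: _with(c, encoder__type="gat"),
    "without_attention_layer": lambda c: _with(c, fusion__attention=False),
    "predict_by_gcn": lambda c: _with(c, heads__use_mlp_head=False),
    "without_structural_features": lambda c: _with(c, enhancement__structural=False),
    "without_node2vec_embedding": lambda c: _with(c, enhancement__walks=False),
    "without_teacher_model": lambda c: _with(c, enhancement__teacher=False,
                                             loss__lambda_kd=0.0),
    "teacher_logits_only": lambda c: _with(c, enhancement__teacher=True,
                                           loss__lambda_kd=0.0),
    "distillation_loss_only": lambda c: _with(c, enhancement__teacher=False),
    "without_feature_enhancement": lambda c: _with(
        c, enhancement__structural=False, enhancement__walks=False,
        enhancement__teacher=False),
}


def run_ablation(variant: str, graph, omics, labels, bundle, cfg, plan,
                 student_epochs=None, teacher_epochs=None) -> MetricReport:
    if variant not in ABLATION_REGISTRY:
        raise ValueError(
            f"unknown ablation variant {variant!r}; known: "
            f"{sorted(ABLATION_REGISTRY)}")
    mutated = ABLATION_REGISTRY[variant](cfg)
    return cross_validate(graph, omics, labels, bundle, mutated, plan,
                          student_epochs=student_epochs,
                          teacher_epochs=teacher_epochs)
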