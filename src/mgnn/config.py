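"""Run configuration: every architectural and training hyperparameter,
YAML-serializable, with ablation toggles.

Defaults follow the reference setting: encoder widths 96/256, projection
128, six 200-wide classifier layers, dropout 0.2, AdamW with learning rate
5.5e-4 and weight decay 8e-5, 900 epochs, distillation weight 0.5, student
ensemble of six with integration temperature 0.08.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .encoders import AugmentationConfig
from .enhancement import WalkParams
from .objectives import LossConfig

ALL_BLOCKS = ("mutation", "expression", "methylation", "cnv")


@dataclass
class EncoderConfig:
    hidden1: int = 96
    hidden2: int = 256
    type: str = "residual_gcn"          # residual_gcn | gat | sage
    shared: bool = False                # single shared encoder over all blocks
    expression_pair_input: bool = False


@dataclass
class FusionConfig:
    attention: bool = True
    d_a: int = 64
    activation: str = "tanh"


@dataclass
class EnhancementConfig:
    structural: bool = True
    walks: bool = True
    teacher: bool = True
    walk_params: WalkParams = field(default_factory=WalkParams)


@dataclass
class HeadConfig:
    projection_dim: int = 128
    gcn_width: int = 200
    gcn_depth: int = 6
    mlp_widths: tuple[int, int, int] = (256, 128, 64)
    use_mlp_head: bool = True


@dataclass
class TrainConfig:
    lr: float = 0.00055
    weight_decay: float = 8e-5
    epochs: int = 900
    dropout: float = 0.2
    n_student_ensemble: int = 6
    ensemble_temperature: float = 0.08
    ensemble_mode: str = "softmax"      # softmax | mean
    val_fraction: float = 0.1           # carved from train labels for ensemble weights
    amp: bool = False                   # accepted for config parity; no-op here
    seed: int = 0


@dataclass
class TeacherTrainConfig:
    """High-capacity teacher: 6 GCN classifier layers (128 then 512 wide),
    1200 epochs, lr 3e-4, weight decay 5e-5, dropout 0.15, early-stopping
    patience 200 on validation AUPRC, parameter EMA decay 0.995, ensemble
    of 10 seeds."""

    classifier_widths: tuple[int, ...] = (128, 512, 512, 512, 512, 512)
    epochs: int = 1200
    lr: float = 0.0003
    weight_decay: float = 5e-5
    dropout: float = 0.15
    patience: int = 200
    ema_decay: float = 0.995
    n_teachers: int = 10
    val_fraction: float = 0.1
    per_fold: bool = True               # retrain teachers inside each CV fold


@dataclass
class ModelConfig:
    blocks: tuple[str, ...] = ALL_BLOCKS
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    heads: HeadConfig = field(default_factory=HeadConfig)
    augment: AugmentationConfig = field(default_factory=AugmentationConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    teacher: TeacherTrainConfig = field(default_factory=TeacherTrainConfig)

    def __post_init__(self):
        unknown = set(self.blocks) - set(ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown omics blocks: {sorted(unknown)}")
        if not self.blocks:
            raise ValueError("at least one omics block must be active")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ModelConfig":
        def build(klass, data):
            if not isinstance(data, dict):
                return data
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in data:
                    continue
                val = data[f.name]
                if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
                    val = build(_NESTED[f.name], val)
                elif isinstance(val, list):
                    val = tuple(val)
                kwargs[f.name] = val
            return klass(**kwargs)

        return build(cls, raw)


_NESTED = {
    "encoder": EncoderConfig,
    "fusion": FusionConfig,
    "enhancement": EnhancementConfig,
    "heads": HeadConfig,
    "augment": AugmentationConfig,
    "loss": LossConfig,
    "train": TrainConfig,
    "teacher": TeacherTrainConfig,
    "walk_params": WalkParams,
}
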