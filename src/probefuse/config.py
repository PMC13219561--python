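"""Run-level configuration: one serializable object drives a whole run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .backbone import BackboneConfig
from .fusion import FusionConfig
from .lora import LoRAConfig


@dataclass(frozen=True)
class TrainingConfig:
    """Episodic adaptation hyperparameters.

    The head learning rate is scaled linearly with task complexity:
    ``head_lr = head_lr_base * n_way / head_lr_ref_n``. Adapters and the
    fusion module use the smaller, steadier ``adapter_lr``. All groups follow
    a cosine-annealed schedule over `steps` with global gradient-norm
    clipping at `clip_norm`.
    """

    steps: int = 50
    adapter_lr: float = 2e-3
    head_lr_base: float = 2e-2
    head_lr_ref_n: int = 5
    clip_norm: float = 1.0
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if min(self.adapter_lr, self.head_lr_base) < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")

    def head_lr(self, n_way: int) -> float:
        return self.head_lr_base * n_way / self.head_lr_ref_n


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run, serializable to YAML."""

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    lora: LoRAConfig = field(default_factory=LoRAConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    n_selected: int = 3       # K_s
    n_tasks: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_selected <= self.backbone.n_layers:
            raise ValueError(
                f"n_selected={self.n_selected} outside "
                f"1..{self.backbone.n_layers}"
            )
        if self.fusion.n_selected != self.n_selected:
            raise ValueError("fusion.n_selected must equal n_selected")
        if self.fusion.feature_dim != self.backbone.hidden_dim:
            raise ValueError("fusion.feature_dim must equal backbone width")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def sub(klass, key):
            payload = dict(raw.get(key) or {})
            known = {f.name for f in dataclasses.fields(klass)}
            payload = {k: v for k, v in payload.items() if k in known}
            if klass is LoRAConfig and "targets" in payload:
                payload["targets"] = tuple(payload["targets"])
            return klass(**payload)

        return cls(
            backbone=sub(BackboneConfig, "backbone"),
            lora=sub(LoRAConfig, "lora"),
            fusion=sub(FusionConfig, "fusion"),
            training=sub(TrainingConfig, "training"),
            n_selected=raw.get("n_selected", 3),
            n_tasks=raw.get("n_tasks", 10),
            seed=raw.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
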