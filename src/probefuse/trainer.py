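"""Episodic adaptation: train adapters, fusion and head on the support set.

Per task the pipeline is: probe the frozen backbone with the Fisher proxy and
select the top-K_s layers; inject low-rank adapters; minimize cross-entropy
of the support set with AdamW over exactly the trainable partition
(adapters | fusion | head) under a cosine-annealed learning-rate schedule
with global gradient clipping; then report macro one-vs-rest AUROC and
accuracy on the held-out query set. The query set is never touched before
evaluation, and every base backbone weight is bit-identical afterwards.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import Backbone, build_backbone
from .config import RunConfig, TrainingConfig
from .episodes import Episode
from .fisher import SelectionResult, probe_backbone
from .fusion import FusionState, fuse, init_fusion
from .lora import inject_lora
from .metrics import accuracy, multiclass_auroc


class ClassifierHead:
    """Final linear classifier d -> N on the fused unit-norm feature."""

    def __init__(self, feature_dim: int, n_classes: int):
        self.weight = Tensor(np.zeros((n_classes, feature_dim)),
                             requires_grad=True, name="head.weight")
        self.bias = Tensor(np.zeros(n_classes), requires_grad=True,
                           name="head.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.weight, self.bias)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


@dataclass
class TrainablePartition:
    """The disjoint trainable groups; everything else stays frozen."""

    lora: list[Tensor]
    fusion: list[Tensor]
    head: list[Tensor]

    def __post_init__(self):
        ids = [id(t) for t in self.lora + self.fusion + self.head]
        if len(ids) != len(set(ids)):
            raise AssertionError("trainable groups are not disjoint")
        for t in self.all():
            if not t.requires_grad:
                raise AssertionError(f"{t.name or t} is not marked trainable")

    def all(self) -> list[Tensor]:
        return self.lora + self.fusion + self.head

    def counts(self) -> dict[str, int]:
        return {
            "lora": sum(t.size for t in self.lora),
            "fusion": sum(t.size for t in self.fusion),
            "head": sum(t.size for t in self.head),
            "total": sum(t.size for t in self.all()),
        }


def build_trainable_partition(backbone: Backbone, fusion_state: FusionState,
                              head: ClassifierHead) -> TrainablePartition:
    """Collect adapter, fusion and head tensors; verify the frozen complement."""
    if backbone.lora_adapters is None:
        raise RuntimeError("no adapters injected; build the partition after "
                           "inject_lora")
    lora_params = [p for a in backbone.lora_adapters for p in a.parameters()]
    for p in backbone.parameters():
        if p.requires_grad:
            raise AssertionError(f"backbone tensor {p.name} is not frozen")
    return TrainablePartition(lora=lora_params,
                              fusion=fusion_state.parameters(),
                              head=head.parameters())


class FewShotModel:
    """Adapted backbone + selected layers + fusion + head, end to end."""

    def __init__(self, backbone: Backbone, selection: SelectionResult,
                 fusion_state: FusionState, head: ClassifierHead):
        self.backbone = backbone
        self.selection = selection
        self.fusion_state = fusion_state
        self.head = head

    def forward(self, images, training: bool = False):
        feats = self.backbone.forward_features(images)
        selected = [feats.pooled[l - 1] for l in self.selection.selected]
        fused = fuse(selected, self.fusion_state, training=training)
        return self.head(fused.output), fused


class AdamW:
    """Decoupled-weight-decay Adam over named parameter groups.

    Each group carries its own base rate; `lr_scale` (the cosine factor) is
    applied uniformly at every step.
    """

    def __init__(self, groups: dict[str, tuple[list[Tensor], float]],
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.state = {id(p): (np.zeros_like(p.data), np.zeros_like(p.data))
                      for params, _ in groups.values() for p in params}

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for params, base_lr in self.groups.values():
            lr = base_lr * lr_scale
            for p in params:
                if p.grad is None:
                    continue
                m, v = self.state[id(p)]
                m[:] = self.b1 * m + (1 - self.b1) * p.grad
                v[:] = self.b2 * v + (1 - self.b2) * p.grad**2
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                p.data = p.data - lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for params, _ in self.groups.values():
            for p in params:
                p.grad = None


def cosine_lr_scale(step: int, total_steps: int) -> float:
    """Cosine annealing factor: 1 at step 0, ~0 at the final step."""
    return 0.5 * (1.0 + np.cos(np.pi * step / total_steps))


def clip_gradients(params: list[Tensor], clip_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most clip_norm."""
    sq = sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
    norm = np.sqrt(sq)
    if norm > clip_norm:
        scale = clip_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return float(norm)


def train_episode(episode: Episode, model: FewShotModel,
                  partition: TrainablePartition,
                  config: TrainingConfig) -> dict:
    """Adapt the trainable partition on the support set.

    Returns a trace dict with per-step support loss, pre-clip gradient norms
    and learning-rate scale. Only support images are ever forwarded.
    """
    if len(episode.support_labels) == 0:
        raise ValueError("empty support set")
    n_way = episode.n_way
    optimizer = AdamW(
        groups={
            "lora": (partition.lora, config.adapter_lr),
            "fusion": (partition.fusion, config.adapter_lr),
            "head": (partition.head, config.head_lr(n_way)),
        },
        weight_decay=config.weight_decay,
    )
    images, labels = episode.support
    losses, grad_norms, lr_scales = [], [], []
    for step in range(config.steps):
        optimizer.zero_grad()
        logits, _ = model.forward(images, training=True)
        loss = ad.cross_entropy(logits, labels)
        loss.backward()
        grad_norms.append(clip_gradients(partition.all(), config.clip_norm))
        scale = cosine_lr_scale(step, config.steps)
        optimizer.step(lr_scale=scale)
        losses.append(loss.item())
        lr_scales.append(scale)
    return {"loss": losses, "grad_norm": grad_norms, "lr_scale": lr_scales}


def evaluate_query(model: FewShotModel, episode: Episode) -> dict:
    """Softmax-score the query set; macro one-vs-rest AUROC plus accuracy."""
    from scipy.special import softmax as _softmax

    with ad.no_grad():
        logits, _ = model.forward(episode.query_images, training=False)
    scores = _softmax(logits.numpy(), axis=1)
    y = episode.query_labels
    if len(np.unique(y)) < 2:
        warnings.warn("query has a single class; AUROC undefined", stacklevel=2)
        auroc, per_class = None, {}
    else:
        auroc, per_class = multiclass_auroc(y, scores, return_per_class=True)
    return {
        "auroc": auroc,
        "accuracy": accuracy(y, scores),
        "per_class_auroc": per_class,
    }


def parameter_report(backbone: Backbone, partition: TrainablePartition) -> dict:
    """Trainable budget: raw counts, millions, percent of the frozen backbone."""
    from .backbone import count_parameters

    counts = partition.counts()
    backbone_total = count_parameters(backbone.config)
    return {
        **counts,
        "backbone_frozen": backbone_total,
        "total_millions": round(counts["total"] / 1e6, 2),
        "percent_trainable": 100.0 * counts["total"] / backbone_total,
    }


def run_task(episode: Episode, config: RunConfig, seed: int) -> dict:
    """Full probe -> select -> inject -> train -> evaluate pipeline, seeded.

    The Fisher probe runs on the frozen, unadapted backbone; adapters are
    injected afterwards, so the probe-phase and step-0 adapted model agree.
    """
    timings = {}
    t0 = time.perf_counter()
    backbone = build_backbone(config.backbone, seed=seed)
    frozen_before = backbone.state_snapshot()
    selection = probe_backbone(backbone, episode, config.n_selected, seed=seed)
    timings["probe"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    import dataclasses as _dc
    inject_lora(backbone, _dc.replace(config.lora, seed=seed))
    fusion_state = init_fusion(config.fusion, seed=seed)
    head = ClassifierHead(config.backbone.hidden_dim, episode.n_way)
    partition = build_trainable_partition(backbone, fusion_state, head)
    model = FewShotModel(backbone, selection, fusion_state, head)
    train_cfg = _dc.replace(config.training, seed=seed)
    trace = train_episode(episode, model, partition, train_cfg)
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    metrics = evaluate_query(model, episode)
    timings["eval"] = time.perf_counter() - t0

    frozen_after = backbone.state_snapshot()
    if not all(np.array_equal(a, b)
               for a, b in zip(frozen_before, frozen_after)):
        raise AssertionError("frozen backbone weights changed during training")

    return {
        "seed": seed,
        "selected_layers": selection.selected,
        "layer_scores": selection.table.normalized.tolist(),
        "loss_trace": trace["loss"],
        "grad_norms": trace["grad_norm"],
        "metrics": metrics,
        "parameters": parameter_report(backbone, partition),
        "timings": timings,
    }
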