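"""Low-rank adapters on the frozen backbone's attention projections.

A frozen projection ``W0`` is augmented with a trainable low-rank branch so
the effective weight becomes ``W' = W0 + scaling * B @ A`` with
``A in R[r, d_in]`` and ``B in R[d_out, r]``. ``B`` starts at zero, so an
adapted model is exactly the base model until training moves the branch.
The branch can be merged into the dense weight for inference and unmerged to
restore the original.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import Backbone


class LoRAStateError(RuntimeError):
    """Raised on invalid adapter state transitions (double inject/merge)."""


@dataclass(frozen=True)
class LoRAConfig:
    rank: int = 8
    targets: tuple[str, ...] = ("query", "key", "value")
    scaling: float = 1.0
    init_std: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        bad = set(self.targets) - {"query", "key", "value"}
        if bad:
            raise ValueError(f"unknown adapter targets: {sorted(bad)}")
        if self.scaling <= 0:
            raise ValueError("scaling must be positive")


class LoRAAdapter:
    """One low-rank branch wrapped around a frozen dense projection."""

    def __init__(self, base, rank: int, scaling: float,
                 rng: np.random.Generator, init_std: float, name: str = ""):
        d_out, d_in = base.weight.shape
        if rank >= min(d_in, d_out):
            warnings.warn(
                f"adapter rank {rank} is not small relative to "
                f"({d_in}, {d_out}); low-rank assumption violated",
                stacklevel=2,
            )
        self.base = base
        self.rank = rank
        self.scaling = float(scaling)
        self.name = name
        self.A = Tensor(rng.normal(0.0, init_std, size=(rank, d_in)),
                        requires_grad=True, name=f"{name}.A")
        self.B = Tensor(np.zeros((d_out, rank)),
                        requires_grad=True, name=f"{name}.B")
        self.merged = False

    def delta(self) -> np.ndarray:
        """The dense update scaling * B @ A."""
        return self.scaling * (self.B.data @ self.A.data)

    def __call__(self, x: Tensor) -> Tensor:
        if self.merged:
            return ad.linear(x, self.base.weight, self.base.bias)
        base_out = ad.linear(x, self.base.weight, self.base.bias)
        branch = ad.matmul(ad.matmul(x, ad.transpose(self.A)),
                           ad.transpose(self.B)) * self.scaling
        return base_out + branch

    def merge(self) -> "LoRAAdapter":
        """Fold the branch into the dense weight (single-matrix forward)."""
        if self.merged:
            raise LoRAStateError("adapter already merged")
        self.base.weight.data = self.base.weight.data + self.delta()
        self.merged = True
        return self

    def unmerge(self) -> "LoRAAdapter":
        """Restore the original dense weight."""
        if not self.merged:
            raise LoRAStateError("adapter is not merged")
        self.base.weight.data = self.base.weight.data - self.delta()
        self.merged = False
        return self

    def parameters(self) -> list[Tensor]:
        return [self.A, self.B]

    def n_parameters(self) -> int:
        return self.A.size + self.B.size


def lora_delta(adapter: LoRAAdapter) -> np.ndarray:
    return adapter.delta()


def inject_lora(backbone: Backbone, config: LoRAConfig) -> list[LoRAAdapter]:
    """Wrap each targeted attention projection of every layer in place.

    Returns the adapters in layer order (query, key, value within a layer).
    The base weights stay frozen; only A and B are trainable, and B = 0 means
    the forward pass is unchanged at injection time.
    """
    if backbone.lora_adapters is not None:
        raise LoRAStateError("backbone already has adapters injected")
    rng = np.random.default_rng(config.seed)
    short = {"query": "q", "key": "k", "value": "v"}
    adapters: list[LoRAAdapter] = []
    for i, blk in enumerate(backbone.blocks):
        attn = blk["attn"]
        for target in ("query", "key", "value"):
            if target not in config.targets:
                continue
            attr = short[target]
            base = getattr(attn, attr)
            adapter = LoRAAdapter(
                base, config.rank, config.scaling, rng, config.init_std,
                name=f"blocks.{i}.attn.{attr}.lora",
            )
            setattr(attn, attr, adapter)
            adapters.append(adapter)
    backbone.lora_adapters = adapters
    return adapters


def count_lora_parameters(n_layers: int, d_in: int, d_out: int,
                          rank: int, n_targets: int = 3) -> int:
    """Closed-form trainable entry count: n_targets * L * r * (d_in + d_out)."""
    if min(n_layers, d_in, d_out, rank, n_targets) <= 0:
        raise ValueError("all arguments must be positive")
    return n_targets * n_layers * rank * (d_in + d_out)


def adapter_state(adapters: list[LoRAAdapter]) -> dict[str, np.ndarray]:
    """Flat named-tensor export of all adapter weights."""
    out = {}
    for a in adapters:
        out[f"{a.name}.A"] = a.A.data.copy()
        out[f"{a.name}.B"] = a.B.data.copy()
    return out


def load_adapter_state(adapters: list[LoRAAdapter],
                       state: dict[str, np.ndarray]) -> None:
    for a in adapters:
        a.A.data = np.asarray(state[f"{a.name}.A"], dtype=np.float64).copy()
        a.B.data = np.asarray(state[f"{a.name}.B"], dtype=np.float64).copy()
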