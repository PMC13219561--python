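"""Attention-guided multiscale fusion of selected-layer features.

Features pooled from the ``K_s`` selected transformer layers are (1) aligned
by one shared linear projection followed by LeakyReLU and L2 normalization,
(2) pre-scaled by learnable static per-layer weights initialized as the
descending sequence linspace(1.5, 0.5, K_s), (3) stacked and aggregated by
multi-head cross-attention in which a single learned query attends over the
K_s stack positions (K = F_stack @ W_K, V = F_stack @ W_V, per-head softmax
with 1 / sqrt(d_k) scaling, no output projection), and (4) passed through
LeakyReLU and L2-normalized, so the classifier downstream operates on a unit
direction vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass(frozen=True)
class FusionConfig:
    n_selected: int = 3          # K_s, number of fused layers
    feature_dim: int = 32        # d, backbone width
    n_heads: int = 8
    dropout: float = 0.1
    leaky_slope: float = 0.1

    def __post_init__(self):
        if self.n_selected < 1:
            raise ValueError("n_selected (K_s) must be >= 1")
        if self.feature_dim % self.n_heads != 0:
            raise ValueError(
                f"feature_dim={self.feature_dim} not divisible by "
                f"n_heads={self.n_heads}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.feature_dim // self.n_heads


def static_weight_init(k: int) -> np.ndarray:
    """Descending sequence 1.5 -> 0.5; a single layer takes the start value."""
    if k == 1:
        return np.array([1.5])
    return np.linspace(1.5, 0.5, k)


class FusionState:
    """Trainable tensors of the fusion module (all members of theta_fusion)."""

    def __init__(self, config: FusionConfig, seed: int = 0):
        self.config = config
        d, k = config.feature_dim, config.n_selected
        rng = np.random.default_rng(seed)
        xavier = np.sqrt(2.0 / (d + d))
        self.proj_weight = Tensor(rng.normal(0, xavier, size=(d, d)),
                                  requires_grad=True, name="fusion.proj.weight")
        self.proj_bias = Tensor(np.zeros(d), requires_grad=True,
                                name="fusion.proj.bias")
        self.static_weights = Tensor(static_weight_init(k), requires_grad=True,
                                     name="fusion.static_weights")
        # Xavier normal for the learned query (fan_in = fan_out = d)
        self.query = Tensor(rng.normal(0, xavier, size=(1, d)),
                            requires_grad=True, name="fusion.query")
        self.key_weight = Tensor(rng.normal(0, xavier, size=(d, d)),
                                 requires_grad=True, name="fusion.key.weight")
        self.value_weight = Tensor(rng.normal(0, xavier, size=(d, d)),
                                   requires_grad=True, name="fusion.value.weight")
        self._rng = np.random.default_rng(seed + 1)  # dropout noise

    def parameters(self) -> list[Tensor]:
        return [self.proj_weight, self.proj_bias, self.static_weights,
                self.query, self.key_weight, self.value_weight]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}


def init_fusion(config: FusionConfig, seed: int = 0) -> FusionState:
    """Deterministically initialize all fusion tensors from `seed`."""
    return FusionState(config, seed=seed)


@dataclass
class FusedFeature:
    """Intermediate and final products of one fusion pass (batched)."""

    aligned: Tensor          # [batch, K_s, d], unit rows
    scaled: Tensor           # [batch, K_s, d]
    attention_weights: Tensor  # [batch, n_heads, K_s]
    attended: Tensor         # [batch, d], pre-activation attention output
    output: Tensor           # [batch, d], unit rows


def project_and_normalize(features: Tensor, state: FusionState) -> Tensor:
    """Shared projection -> LeakyReLU -> L2 normalization.

    Accepts [d], [batch, d] or [batch, K_s, d]; an all-zero activation row
    stays a zero vector (with a warning) rather than dividing by zero.
    """
    act = ad.leaky_relu(
        ad.linear(features, state.proj_weight, state.proj_bias),
        state.config.leaky_slope,
    )
    norms = np.sqrt((act.data**2).sum(axis=-1))
    if np.any(norms == 0.0):
        warnings.warn("zero-activation feature vector; returned as zeros",
                      stacklevel=2)
    return ad.l2_normalize(act, axis=-1)


def fuse(features, state: FusionState, training: bool = False) -> FusedFeature:
    """Fuse the K_s selected-layer pooled features of a batch.

    `features` is a list of K_s tensors, each [batch, d] (or [d] for a single
    sample), ordered to match the static weights. Attention dropout is active
    only when `training` is true.
    """
    cfg = state.config
    k, d, h = cfg.n_selected, cfg.feature_dim, cfg.n_heads
    dk = d // h
    if len(features) != k:
        raise ValueError(f"expected {k} feature tensors, got {len(features)}")
    feats = [f if isinstance(f, Tensor) else Tensor(f) for f in features]
    single = feats[0].ndim == 1
    if single:
        feats = [ad.reshape(f, (1, d)) for f in feats]
    b = feats[0].shape[0]

    stacked = ad.stack(feats, axis=1)              # [b, K_s, d]
    aligned = project_and_normalize(stacked, state)
    scaled = aligned * ad.reshape(state.static_weights, (1, k, 1))

    # keys/values from the stack, query shared across the batch
    keys = ad.matmul(scaled, state.key_weight)      # [b, K_s, d]
    values = ad.matmul(scaled, state.value_weight)  # [b, K_s, d]
    k_heads = ad.transpose(ad.reshape(keys, (b, k, h, dk)), (0, 2, 1, 3))
    v_heads = ad.transpose(ad.reshape(values, (b, k, h, dk)), (0, 2, 1, 3))
    q_heads = ad.reshape(state.query, (1, h, 1, dk))

    scores = ad.matmul(q_heads, ad.transpose(k_heads, (0, 1, 3, 2))) * (dk**-0.5)
    weights = ad.softmax(scores, axis=-1)           # [b, h, 1, K_s]
    if training and cfg.dropout > 0.0:
        keep = (state._rng.random(weights.shape) >= cfg.dropout)
        weights = weights * Tensor(keep / (1.0 - cfg.dropout))
    attended = ad.reshape(ad.matmul(weights, v_heads), (b, d))
    output = ad.l2_normalize(ad.leaky_relu(attended, cfg.leaky_slope), axis=-1)

    attn_w = ad.reshape(weights, (b, h, k))
    if single:
        aligned = ad.reshape(aligned, (k, d))
        scaled = ad.reshape(scaled, (k, d))
        attended = ad.reshape(attended, (d,))
        output = ad.reshape(output, (d,))
    return FusedFeature(aligned=aligned, scaled=scaled,
                        attention_weights=attn_w, attended=attended,
                        output=output)
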