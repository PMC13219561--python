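"""Configurable ViT-style image encoder exposing every layer's representation.

The encoder is a standard pre-norm vision transformer: patch embedding with a
learned class token and learned positional embeddings, then ``L`` blocks of
(LayerNorm -> multi-head self-attention -> residual, LayerNorm -> GELU MLP ->
residual), and a final LayerNorm. A single forward pass caches the hidden
state of *every* block together with its pooled feature (the class token row,
or the token mean), which is what the downstream layer-probing and fusion
stages consume.

All weights are frozen by default; adaptation happens exclusively through
low-rank branches attached elsewhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent backbone configuration."""


@dataclass(frozen=True)
class BackboneConfig:
    """Architectural hyperparameters of the encoder.

    ``pooling`` selects how a layer's hidden state is reduced to one vector
    per image: ``"cls_token"`` takes the class-token row, ``"mean_tokens"``
    averages all tokens.
    """

    n_layers: int = 6
    hidden_dim: int = 32
    n_heads: int = 4
    mlp_dim: int = 64
    patch_size: int = 8
    image_size: int = 32
    n_channels: int = 1
    pooling: str = "cls_token"
    init_std: float | None = None  # default: hidden_dim ** -0.5

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ConfigurationError(
                f"image_size={self.image_size} is not divisible by "
                f"patch_size={self.patch_size}"
            )
        if self.n_heads > 0 and self.hidden_dim % self.n_heads != 0:
            raise ConfigurationError(
                f"hidden_dim={self.hidden_dim} is not divisible by "
                f"n_heads={self.n_heads}"
            )
        for name in ("n_layers",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        for name in ("hidden_dim", "n_heads", "mlp_dim", "patch_size",
                     "image_size", "n_channels"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.pooling not in ("cls_token", "mean_tokens"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def n_tokens(self) -> int:
        # the class token is always materialized; mean pooling includes it
        return self.n_patches + 1

    @property
    def head_dim(self) -> int:
        return self.hidden_dim // self.n_heads

    @classmethod
    def from_yaml(cls, path) -> "BackboneConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LayerFeatures:
    """Per-layer hidden states and pooled features from one forward pass."""

    hidden_states: list[Tensor]  # each [batch, T, d]
    pooled: list[Tensor]         # each [batch, d]

    def __len__(self) -> int:
        return len(self.hidden_states)


def count_parameters(config: BackboneConfig) -> int:
    """Exact scalar-parameter count of the encoder (no task head).

    Components: patch projection (weight + bias), class token, positional
    embeddings (one per token, class token included), per block two
    LayerNorms, q/k/v/out projections with biases and the two-layer MLP with
    biases, plus the final LayerNorm.
    """
    d, L = config.hidden_dim, config.n_layers
    patch_in = config.patch_size**2 * config.n_channels
    total = d * patch_in + d          # patch embedding
    total += d                        # class token
    total += config.n_tokens * d      # positional embeddings
    per_layer = 2 * (2 * d)           # two LayerNorms (scale + shift)
    per_layer += 4 * (d * d + d)      # q, k, v, out projections
    per_layer += d * config.mlp_dim + config.mlp_dim  # MLP up
    per_layer += config.mlp_dim * d + d               # MLP down
    total += L * per_layer
    total += 2 * d                    # final LayerNorm
    return total


def parameter_count_report(config: BackboneConfig) -> dict[str, int]:
    """Per-component parameter counts, JSON-serializable."""
    d = config.hidden_dim
    patch_in = config.patch_size**2 * config.n_channels
    per_layer = 4 * d + 4 * (d * d + d) + d * config.mlp_dim + config.mlp_dim \
        + config.mlp_dim * d + d
    return {
        "patch_embedding": d * patch_in + d,
        "class_token": d,
        "positional_embedding": config.n_tokens * d,
        "encoder_blocks": config.n_layers * per_layer,
        "final_norm": 2 * d,
        "total": count_parameters(config),
    }


def _trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Truncated normal at +/- 2 std, via resampling."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x


class AttentionProjections:
    """The four dense projections of one self-attention block.

    ``q``/``k``/``v``/``out`` are plain linear layers; the low-rank adapter
    machinery may wrap q, k, v in place.
    """

    def __init__(self, layers: dict):
        self.q = layers["q"]
        self.k = layers["k"]
        self.v = layers["v"]
        self.out = layers["out"]


class Linear:
    """Dense layer holding a frozen-by-default weight [out, in] and bias."""

    def __init__(self, weight: Tensor, bias: Tensor):
        self.weight = weight
        self.bias = bias

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.weight, self.bias)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Backbone:
    """Frozen pre-norm vision transformer with per-layer feature access."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        std = config.init_std if config.init_std is not None \
            else config.hidden_dim ** -0.5
        d = config.hidden_dim

        def lin(d_out, d_in, name):
            w = Tensor(_trunc_normal(rng, (d_out, d_in), std), name=f"{name}.weight")
            b = Tensor(np.zeros(d_out), name=f"{name}.bias")
            return Linear(w, b)

        patch_in = config.patch_size**2 * config.n_channels
        self.patch_embed = lin(d, patch_in, "patch_embed")
        self.cls_token = Tensor(_trunc_normal(rng, (1, 1, d), std), name="cls_token")
        self.pos_embed = Tensor(
            _trunc_normal(rng, (1, config.n_tokens, d), std), name="pos_embed"
        )
        self.blocks = []
        for i in range(config.n_layers):
            blk = {
                "ln1": (Tensor(np.ones(d), name=f"blocks.{i}.ln1.weight"),
                        Tensor(np.zeros(d), name=f"blocks.{i}.ln1.bias")),
                "attn": AttentionProjections({
                    "q": lin(d, d, f"blocks.{i}.attn.q"),
                    "k": lin(d, d, f"blocks.{i}.attn.k"),
                    "v": lin(d, d, f"blocks.{i}.attn.v"),
                    "out": lin(d, d, f"blocks.{i}.attn.out"),
                }),
                "ln2": (Tensor(np.ones(d), name=f"blocks.{i}.ln2.weight"),
                        Tensor(np.zeros(d), name=f"blocks.{i}.ln2.bias")),
                "mlp_up": lin(config.mlp_dim, d, f"blocks.{i}.mlp_up"),
                "mlp_down": lin(d, config.mlp_dim, f"blocks.{i}.mlp_down"),
            }
            self.blocks.append(blk)
        self.final_norm = (Tensor(np.ones(d), name="final_norm.weight"),
                           Tensor(np.zeros(d), name="final_norm.bias"))
        self.lora_adapters = None  # set by the lora module on injection

    # ------------------------------------------------------------- inventory
    def parameters(self) -> list[Tensor]:
        """All base (backbone) tensors, in a stable order."""
        params = self.patch_embed.parameters() + [self.cls_token, self.pos_embed]
        for blk in self.blocks:
            params += list(blk["ln1"])
            attn = blk["attn"]
            for proj in (attn.q, attn.k, attn.v, attn.out):
                # an injected adapter wraps the frozen base projection
                base = getattr(proj, "base", proj)
                params += base.parameters()
            params += list(blk["ln2"])
            params += blk["mlp_up"].parameters() + blk["mlp_down"].parameters()
        params += list(self.final_norm)
        return params

    def state_snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    # --------------------------------------------------------------- forward
    def _patchify(self, images: np.ndarray) -> np.ndarray:
        """[B, C, H, W] -> [B, n_patches, patch_size**2 * C]."""
        cfg = self.config
        b, c, h, w = images.shape
        p = cfg.patch_size
        x = images.reshape(b, c, h // p, p, w // p, p)
        x = x.transpose(0, 2, 4, 3, 5, 1)  # B, gh, gw, p, p, C
        return x.reshape(b, cfg.n_patches, p * p * c)

    def _attention(self, x: Tensor, attn: AttentionProjections) -> Tensor:
        cfg = self.config
        b, t, d = x.shape
        h, dk = cfg.n_heads, cfg.head_dim

        def split_heads(z: Tensor) -> Tensor:
            return ad.transpose(ad.reshape(z, (b, t, h, dk)), (0, 2, 1, 3))

        q = split_heads(attn.q(x))
        k = split_heads(attn.k(x))
        v = split_heads(attn.v(x))
        scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * (dk**-0.5)
        weights = ad.softmax(scores, axis=-1)
        ctx = ad.matmul(weights, v)  # [b, h, t, dk]
        ctx = ad.reshape(ad.transpose(ctx, (0, 2, 1, 3)), (b, t, d))
        return attn.out(ctx)

    def forward_features(self, images) -> LayerFeatures:
        """Run the encoder once, caching every layer's output.

        ``images`` is [batch, channels, H, W]. The pooled feature of layer
        l is the class-token row of its output hidden state (after the
        block's residual addition, before the final norm) under cls_token
        pooling, or the mean over tokens under mean_tokens pooling.
        """
        cfg = self.config
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[1:] != (
            cfg.n_channels, cfg.image_size, cfg.image_size
        ):
            raise ValueError(
                f"expected images [batch, {cfg.n_channels}, {cfg.image_size}, "
                f"{cfg.image_size}], got {images.shape}"
            )
        b = images.shape[0]
        patches = Tensor(self._patchify(images))
        tokens = self.patch_embed(patches)  # [b, n_patches, d]
        cls = ad.concat(
            [self.cls_token * Tensor(np.ones((b, 1, 1))), tokens], axis=1
        )
        x = cls + self.pos_embed

        hidden, pooled = [], []
        for blk in self.blocks:
            y = ad.layer_norm(x, *blk["ln1"])
            x = x + self._attention(y, blk["attn"])
            y = ad.layer_norm(x, *blk["ln2"])
            x = x + blk["mlp_down"](ad.gelu(blk["mlp_up"](y)))
            hidden.append(x)
            if cfg.pooling == "cls_token":
                pooled.append(x[:, 0])
            else:
                pooled.append(ad.tmean(x, axis=1))
        return LayerFeatures(hidden_states=hidden, pooled=pooled)


def build_backbone(config: BackboneConfig, seed: int = 0) -> Backbone:
    """Construct a backbone with deterministic seeded initialization."""
    return Backbone(config, seed=seed)


VIT_B16 = BackboneConfig(
    n_layers=12, hidden_dim=768, n_heads=12, mlp_dim=3072,
    patch_size=16, image_size=224, n_channels=3,
)
"""The base-size /16 configuration used for parameter accounting."""
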