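"""Shared fixtures: tiny backbones and episodes, generated at session scope."""

import numpy as np
import pytest

from probefuse import (BackboneConfig, SyntheticSpec, build_backbone,
                       generate_episode, generate_planted_task)

TINY = BackboneConfig(n_layers=2, hidden_dim=16, n_heads=2, mlp_dim=32,
                      patch_size=4, image_size=16, n_channels=1)

SMALL = BackboneConfig()  # L=6, d=32, heads=4, patch 8, 32x32 grayscale


@pytest.fixture(scope="session")
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def small_backbone():
    return build_backbone(SMALL, seed=0)


@pytest.fixture(scope="session")
def texture_episode():
    return generate_episode(SyntheticSpec(n_way=4, k_shot=5, n_query=20,
                                          seed=7))


@pytest.fixture(scope="session")
def planted(small_backbone):
    """A separable task whose labels are planted at layer 3."""
    spec = SyntheticSpec(n_way=4, k_shot=10, n_query=20, seed=11)
    return generate_planted_task(small_backbone, layer=3, spec=spec)
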