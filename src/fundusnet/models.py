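"""Encoder and head factories.

The encoder maps an image batch (N, 3, H, W) to a pooled representation
h (N, h_dim); the projection head maps h to the 128-dimensional embedding
z used by the contrastive loss; the classifier head maps h to two logits
(non-referable, referable).

Two desk-scale encoders are registered: ``small`` (plain conv stack,
default) and ``small_resnet`` (adds a residual block), standing in for the
encoder-architecture comparison at a size trainable on one CPU.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    AvgPool2d,
    Conv2d,
    GlobalAvgPool,
    LayerNorm,
    Linear,
    ReLU,
    Residual,
    Sequential,
)

PROJECTION_DIM = 128

ENCODER_NAMES = ("small", "wide", "small_resnet")


def encoder_h_dim(name: str) -> int:
    if name not in ENCODER_NAMES:
        raise ValueError(f"unknown encoder '{name}'; choose from {ENCODER_NAMES}")
    return 64 if name == "wide" else 32


def build_encoder(name: str, rng: np.random.Generator) -> Sequential:
    if name == "small":
        return Sequential([
            Conv2d(3, 8, 3, "conv1", rng), ReLU(), AvgPool2d(),
            Conv2d(8, 16, 3, "conv2", rng), ReLU(), AvgPool2d(),
            Conv2d(16, 32, 3, "conv3", rng), ReLU(),
            GlobalAvgPool(),
        ])
    if name == "wide":
        return Sequential([
            Conv2d(3, 16, 3, "conv1", rng), ReLU(), AvgPool2d(),
            Conv2d(16, 32, 3, "conv2", rng), ReLU(), AvgPool2d(),
            Conv2d(32, 64, 3, "conv3", rng), ReLU(),
            GlobalAvgPool(),
        ])
    if name == "small_resnet":
        block = Sequential([
            Conv2d(16, 16, 3, "res1a", rng), ReLU(),
            Conv2d(16, 16, 3, "res1b", rng),
        ])
        return Sequential([
            Conv2d(3, 16, 3, "stem", rng), ReLU(), AvgPool2d(),
            Residual(block), ReLU(), AvgPool2d(),
            Conv2d(16, 32, 3, "head_conv", rng), ReLU(),
            GlobalAvgPool(),
        ])
    raise ValueError(f"unknown encoder '{name}'; choose from {ENCODER_NAMES}")


def build_projection_head(h_dim: int, rng: np.random.Generator) -> Sequential:
    """2-layer MLP projecting h to the 128-dim contrastive embedding.

    The input is layer-normalized first: pooled ReLU features are all
    positive and share a large mean direction, which would otherwise start
    every embedding nearly parallel (cosine similarity collapse).
    """
    return Sequential([
        LayerNorm(),
        Linear(h_dim, 64, "proj1", rng), ReLU(),
        Linear(64, PROJECTION_DIM, "proj2", rng),
    ])


def build_classifier_head(h_dim: int, rng: np.random.Generator) -> Sequential:
    return Sequential([Linear(h_dim, 2, "fc", rng)])
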