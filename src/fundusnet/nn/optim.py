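"""Optimizers: Adam for supervised fine-tuning, LARS for large-batch
contrastive pretraining.

LARS rescales each tensor's step by a layer-wise trust ratio
``trust_coefficient * ||w|| / (||g|| + weight_decay * ||w||)``, which keeps
per-layer updates proportional to weight norms and stabilizes training at
large batch sizes.  Biases and other one-dimensional parameters are exempt
from trust-ratio scaling, the usual convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lars_step", "LARS", "Adam"]


def _is_excluded(name: str, arr: np.ndarray) -> bool:
    # biases / normalization scales: 1-D tensors
    return arr.ndim <= 1


def lars_step(
    weights: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    base_lr: float,
    weight_decay: float = 0.0,
    trust_coefficient: float = 0.001,
    momentum_state: dict[str, np.ndarray] | None = None,
    momentum: float = 0.9,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """One LARS update over a dict of named tensors.

    Returns ``(new_weights, new_momentum_state)``; inputs are not mutated.
    Excluded tensors (1-D: biases, norm parameters) take a plain momentum-SGD
    step without trust-ratio scaling.
    """
    if momentum_state is None:
        momentum_state = {k: np.zeros_like(v) for k, v in weights.items()}
    new_w: dict[str, np.ndarray] = {}
    new_m: dict[str, np.ndarray] = {}
    for k, w in weights.items():
        g = grads[k]
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {k}")
        g = g + weight_decay * w
        if _is_excluded(k, w):
            local_lr = 1.0
        else:
            wn = float(np.linalg.norm(w))
            gn = float(np.linalg.norm(g))
            local_lr = trust_coefficient * wn / gn if (wn > 0 and gn > 0) else 1.0
        m = momentum * momentum_state[k] + base_lr * local_lr * g
        new_m[k] = m.astype(w.dtype)
        new_w[k] = (w - m).astype(w.dtype)
    return new_w, new_m


class LARS:
    """Stateful wrapper around :func:`lars_step` bound to a model."""

    def __init__(self, model, base_lr: float, weight_decay: float = 1e-5,
                 trust_coefficient: float = 0.001, momentum: float = 0.9) -> None:
        self.model = model
        self.base_lr = base_lr
        self.weight_decay = weight_decay
        self.trust_coefficient = trust_coefficient
        self.momentum = momentum
        self.state: dict[str, np.ndarray] | None = None

    def step(self) -> None:
        w = self.model.named_params()
        g = self.model.named_grads()
        new_w, self.state = lars_step(
            w, g, self.base_lr, self.weight_decay,
            self.trust_coefficient, self.state, self.momentum,
        )
        self.model.set_params(new_w)


class Adam:
    def __init__(self, model, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        params = model.named_params()
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        params = self.model.named_params()
        grads = self.model.named_grads()
        for k, w in params.items():
            g = grads[k]
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in {k}")
            if self.weight_decay:
                g = g + self.weight_decay * w
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            w -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(w.dtype)
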