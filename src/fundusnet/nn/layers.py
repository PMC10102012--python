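"""Minimal feed-forward layers with manual backpropagation.

All arrays are float32 NCHW (images) or NxD (vectors).  Every layer caches
what its backward pass needs on ``forward`` and accumulates parameter
gradients into ``grads`` on ``backward``.  Parameters are plain numpy
arrays keyed by ``<layer name>.<param>`` so checkpoints are portable,
layer-name-addressable archives.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "AvgPool2d",
    "GlobalAvgPool",
    "UpsampleNearest",
    "Flatten",
    "Residual",
    "Sequential",
]


class Layer:
    """Base class: stateless unless it declares parameters."""

    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def named_params(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.{k}": v for k, v in self.params.items()}

    def named_grads(self) -> dict[str, np.ndarray]:
        return {f"{self.name}.{k}": v for k, v in self.grads.items()}


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """3x3-style convolution via im2col; stride 1, symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, name: str,
                 rng: np.random.Generator, pad: int | None = None) -> None:
        super().__init__()
        self.name = name
        self.k = k
        self.pad = (k // 2) if pad is None else pad
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "W": _he_init(rng, (c_out, c_in, k, k), c_in * k * k),
            "b": np.zeros(c_out, dtype=np.float32),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        # (n, c, k, k, ho, wo) view -> columns (n*ho*wo, c*k*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        wmat = self.params["W"].reshape(self.c_out, -1)
        out = cols @ wmat.T + self.params["b"]
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, p = self.k, self.pad
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.c_out)
        self.grads["W"] += (dmat.T @ cols).reshape(self.params["W"].shape)
        self.grads["b"] += dmat.sum(axis=0)
        dcols = (dmat @ self.params["W"].reshape(self.c_out, -1)).reshape(
            n, ho, wo, c, k, k
        )
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + ho, dj:dj + wo] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, name: str, rng: np.random.Generator) -> None:
        super().__init__()
        self.name = name
        self.params = {
            "W": _he_init(rng, (d_out, d_in), d_in),
            "b": np.zeros(d_out, dtype=np.float32),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += dout.T @ self._x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._y * (1.0 - self._y)).astype(np.float32)


class LayerNorm(Layer):
    """Per-sample standardization over the feature axis of an (N, D) input.

    Parameter-free: removes the shared mean/scale component that otherwise
    collapses all-positive pooled features onto one direction, without
    introducing batch-statistics nondeterminism.
    """

    def __init__(self, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self._xhat.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, istd = self._xhat, self._istd
        d = xhat.shape[1]
        dx = (
            dout
            - dout.mean(axis=1, keepdims=True)
            - xhat * (dout * xhat).mean(axis=1, keepdims=True)
        ) * istd
        return dx.astype(np.float32)


class AvgPool2d(Layer):
    """2x2 average pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
        return d.astype(np.float32)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (
            np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)
        ).astype(np.float32)


class UpsampleNearest(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Residual(Layer):
    """y = x + body(x); body must preserve shape."""

    def __init__(self, body: "Sequential") -> None:
        super().__init__()
        self.body = body

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout + self.body.backward(dout)

    def zero_grad(self) -> None:
        self.body.zero_grad()

    def named_params(self) -> dict[str, np.ndarray]:
        return self.body.named_params()

    def named_grads(self) -> dict[str, np.ndarray]:
        return self.body.named_grads()


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers
        names = [n for lay in layers for n in lay.named_params()]
        if len(names) != len(set(names)):
            raise ValueError("duplicate parameter names in Sequential")

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for lay in self.layers:
            lay.zero_grad()

    def named_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for lay in self.layers:
            out.update(lay.named_params())
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for lay in self.layers:
            out.update(lay.named_grads())
        return out

    def set_params(self, arrays: dict[str, np.ndarray], strict: bool = True) -> None:
        """Copy ``arrays`` into the matching parameters (bit-exact)."""
        own = self.named_params()
        if strict and set(own) != set(arrays):
            missing = sorted(set(own) ^ set(arrays))
            raise KeyError(f"parameter name mismatch: {missing}")
        for k, v in arrays.items():
            if k in own:
                if own[k].shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                own[k][...] = v
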