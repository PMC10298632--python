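"""Minimal numpy neural-network layers with explicit backpropagation.

Everything runs in float64 on (N, C, H, W) batches, where the batch axis is
the slice axis of one exam. Convolution uses an im2col formulation; each
layer caches what its backward pass needs. Gradients accumulate into
``layer.grads`` and are zeroed by the optimizer step.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix."""
    windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, Ho, Wo, k, k) -> (N, Ho, Wo, C, k, k)
    windows = windows.transpose(0, 2, 3, 1, 4, 5)
    n, ho, wo = windows.shape[:3]
    return windows.reshape(n * ho * wo, -1), ho, wo


class Conv2d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.params = {
            "W": rng.normal(0.0, scale, size=(out_channels, in_channels, kernel, kernel)),
            "b": np.zeros(out_channels),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        col, ho, wo = _im2col(xp, self.kernel, self.stride)
        w_mat = self.params["W"].reshape(self.out_channels, -1)
        out = col @ w_mat.T + self.params["b"]
        n = x.shape[0]
        self._cache = (col, xp.shape, ho, wo)
        return out.reshape(n, ho, wo, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, xp_shape, ho, wo = self._cache
        n = dy.shape[0]
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_channels)
        w_mat = self.params["W"].reshape(self.out_channels, -1)
        self.grads["W"] += (dy_mat.T @ col).reshape(self.params["W"].shape)
        self.grads["b"] += dy_mat.sum(axis=0)
        dcol = dy_mat @ w_mat
        # Scatter patches back to the padded input (col2im).
        k, s = self.kernel, self.stride
        dcol = dcol.reshape(n, ho, wo, self.in_channels, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcol[:, :, :, :, i, j]
        p = self.padding
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2d(Layer):
    def __init__(self, kernel: int, stride: int) -> None:
        super().__init__()
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = windows.shape[:4]
        flat = windows.reshape(n, c, ho, wo, k * k)
        self._argmax = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s = self.kernel, self.stride
        n, c, ho, wo = dy.shape
        dx = np.zeros(self._x_shape)
        iy, ix = np.divmod(self._argmax, k)
        grid_i, grid_j = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
        rows = grid_i[None, None] * s + iy
        cols = grid_j[None, None] * s + ix
        nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(dx, (nn[:, :, None, None], cc[:, :, None, None], rows, cols), dy)
        return dx


class AdaptiveAvgPool2d(Layer):
    """Average pooling to a fixed output grid, bins as in standard practice:
    bin i covers [floor(i*H/out), ceil((i+1)*H/out))."""

    def __init__(self, out_size: tuple[int, int]) -> None:
        super().__init__()
        self.out_size = out_size

    @staticmethod
    def _bins(n: int, out: int) -> list[tuple[int, int]]:
        return [(int(np.floor(i * n / out)), int(np.ceil((i + 1) * n / out))) for i in range(out)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self.out_size
        if (h, w) == (oh, ow):
            self._identity = True
            return x
        self._identity = False
        self._x_shape = x.shape
        self._row_bins = self._bins(h, oh)
        self._col_bins = self._bins(w, ow)
        out = np.empty((n, c, oh, ow))
        for i, (r0, r1) in enumerate(self._row_bins):
            for j, (c0, c1) in enumerate(self._col_bins):
                out[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._identity:
            return dy
        dx = np.zeros(self._x_shape)
        for i, (r0, r1) in enumerate(self._row_bins):
            for j, (c0, c1) in enumerate(self._col_bins):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += dy[:, :, i : i + 1, j : j + 1] / area
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{prefix}.{i}.{name}"] = arr
        return out

    def named_grads(self, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.grads.items():
                out[f"{prefix}.{i}.{name}"] = arr
        return out


class Adam:
    """Adaptive-moment optimizer over a named-parameter dict."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, p in self.params.items():
            g = grads[key]
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    @staticmethod
    def zero_grads(grads: dict[str, np.ndarray]) -> None:
        for g in grads.values():
            g[...] = 0.0
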