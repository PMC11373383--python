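"""Minimal feed-forward layer zoo with explicit backpropagation.

Implements exactly the operations the sweep classifiers need — 1-D and
2-D convolution with TensorFlow-style "same" padding, width-2 max
pooling, dense layers, ReLU — on plain numpy arrays.  Forward passes
cache what the matching ``backward`` call needs; parameters accumulate
gradients in place for the optimizer.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> List[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def same_pad(width: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_width, pad_left, pad_right) for "same"-style convolution.

    Output width is ``ceil(width / stride)``; total padding is split with
    the extra element on the right.
    """
    out = -(-width // stride)
    total = max((out - 1) * stride + kernel - width, 0)
    left = total // 2
    return out, left, total - left


def conv_output_width(width: int, kernel: int, stride: int, padding: str) -> int:
    if padding == "same":
        return -(-width // stride)
    if padding == "valid":
        return (width - kernel) // stride + 1 if width >= kernel else 0
    raise ValueError(f"unknown padding {padding!r}")


def _he_init(rng: np.random.Generator, shape: Sequence[int], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: str = "same",
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(
            _he_init(rng, (out_channels, in_channels, kernel), in_channels * kernel)
        )
        self.bias = Parameter(np.zeros(out_channels))
        self._cache = None

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, w = x.shape
        if self.padding == "same":
            out_w, pl, pr = same_pad(w, self.kernel, self.stride)
        else:
            out_w = conv_output_width(w, self.kernel, self.stride, self.padding)
            pl = pr = 0
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        cols = sliding_window_view(xp, self.kernel, axis=2)[:, :, :: self.stride]
        cols = cols[:, :, :out_w]
        y = np.einsum("bcwk,ock->bow", cols, self.weight.value, optimize=True)
        y += self.bias.value[None, :, None]
        self._cache = (cols, xp.shape[2], pl, w)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, wp, pl, w = self._cache
        self.weight.grad += np.einsum("bcwk,bow->ock", cols, grad, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2))
        b = grad.shape[0]
        gx_p = np.zeros((b, self.weight.value.shape[1], wp))
        out_w = grad.shape[2]
        base = np.arange(out_w) * self.stride
        for j in range(self.kernel):
            # positions base+j are distinct for fixed j, so fancy += is safe
            gx_p[:, :, base + j] += np.einsum(
                "bow,oc->bcw", grad, self.weight.value[:, :, j], optimize=True
            )
        return gx_p[:, :, pl : pl + w]


class MaxPool1d(Layer):
    """Width-2, stride-2 max pooling; a trailing odd column is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, w = x.shape
        out_w = w // 2
        if out_w < 1:
            raise ValueError(f"cannot pool width {w} below 1")
        xt = x[:, :, : 2 * out_w].reshape(b, c, out_w, 2)
        idx = xt.argmax(axis=3)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xt, idx[..., None], axis=3)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        b, c, w = shape
        out_w = grad.shape[2]
        gx = np.zeros(shape)
        gxt = gx[:, :, : 2 * out_w].reshape(b, c, out_w, 2)
        np.put_along_axis(gxt, idx[..., None], grad[..., None], axis=3)
        return gx


class Conv2d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        padding: str = "same",
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.weight = Parameter(
            _he_init(
                rng,
                (out_channels, in_channels, kernel, kernel),
                in_channels * kernel * kernel,
            )
        )
        self.bias = Parameter(np.zeros(out_channels))
        self._cache = None

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if self.padding != "same":
            raise ValueError("Conv2d supports 'same' padding only")
        out_h, pt, pb = same_pad(h, self.kernel, self.stride)
        out_w, pl, pr = same_pad(w, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        cols = sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        cols = cols[:, :, :: self.stride, :: self.stride][:, :, :out_h, :out_w]
        y = np.einsum("bchwij,ocij->bohw", cols, self.weight.value, optimize=True)
        y += self.bias.value[None, :, None, None]
        self._cache = (cols, xp.shape, (pt, pl), (h, w))
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xp_shape, (pt, pl), (h, w) = self._cache
        self.weight.grad += np.einsum("bchwij,bohw->ocij", cols, grad, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        b = grad.shape[0]
        gx_p = np.zeros((b, self.weight.value.shape[1], xp_shape[2], xp_shape[3]))
        out_h, out_w = grad.shape[2], grad.shape[3]
        rows = np.arange(out_h) * self.stride
        colsx = np.arange(out_w) * self.stride
        for i in range(self.kernel):
            for j in range(self.kernel):
                gx_p[:, :, rows[:, None] + i, colsx[None, :] + j] += np.einsum(
                    "bohw,oc->bchw", grad, self.weight.value[:, :, i, j], optimize=True
                )
        return gx_p[:, :, pt : pt + h, pl : pl + w]


class MaxPool2d(Layer):
    """2x2, stride-2 max pooling over the two trailing axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        if oh < 1 or ow < 1:
            raise ValueError(f"cannot pool {h}x{w} below 1x1")
        xt = x[:, :, : 2 * oh, : 2 * ow].reshape(b, c, oh, 2, ow, 2)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, oh, ow, 4)
        idx = xt.argmax(axis=4)
        self._cache = (idx, x.shape)
        return np.take_along_axis(xt, idx[..., None], axis=4)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        b, c, h, w = shape
        oh, ow = grad.shape[2], grad.shape[3]
        flat = np.zeros((b, c, oh, ow, 4))
        np.put_along_axis(flat, idx[..., None], grad[..., None], axis=4)
        flat = flat.reshape(b, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros(shape)
        gx[:, :, : 2 * oh, : 2 * ow] = flat.reshape(b, c, 2 * oh, 2 * ow)
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def parameters(self) -> List[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def parameters(self) -> List[Parameter]:
        out: List[Parameter] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
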