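"""Minimal NumPy neural-network layers with explicit backpropagation.

All layers operate on float32 arrays in NCHW layout. Each layer caches
whatever its backward pass needs during ``forward`` and releases it on
``backward``; networks are therefore single-use per forward/backward pair,
exactly like eager-mode frameworks. Parameters are ``Param`` objects holding
``value`` and ``grad`` arrays of identical shape, which the optimizer in
:mod:`lesioncorrect.training` updates in place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "AvgPool2d",
    "Dropout",
    "Linear",
    "Flatten",
    "GlobalAvgPool2d",
    "Sequential",
]


class Param:
    """A trainable tensor: value plus accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base layer: stateless unless it owns Params or running statistics."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patch matrix for a stride-1 'same' conv."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    n, c, h, w = x.shape
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H*W, C*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)


class Conv2d(Layer):
    """Stride-1 'same'-padded 2-D convolution with odd square kernels."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        if kernel % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes only")
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.weight = Param(w, name=f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), name=f"{name}.bias")
        self.kernel = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        cols = _im2col(x, self.kernel)  # (N, HW, C*k*k)
        wmat = self.weight.value.reshape(self.out_ch, -1)  # (O, C*k*k)
        y = cols @ wmat.T + self.bias.value  # (N, HW, O)
        if train:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape(n, self.out_ch, h, w)

    def backward(self, grad):
        cols, xshape = self._cache
        self._cache = None
        n, c, h, w = xshape
        g = grad.reshape(n, self.out_ch, h * w).transpose(0, 2, 1)  # (N, HW, O)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        dw = np.einsum("nho,nhk->ok", g, cols, optimize=True)
        self.weight.grad += dw.reshape(self.weight.shape)
        self.bias.grad += g.sum(axis=(0, 1))
        # dx = 'same' convolution of grad with the 180-degree-rotated, channel-swapped kernel
        w_rot = self.weight.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, k, k)
        gcols = _im2col(grad, self.kernel)  # (N, HW, O*k*k)
        dx = gcols @ w_rot.reshape(c, -1).T  # (N, HW, C)
        return np.ascontiguousarray(dx.transpose(0, 2, 1)).reshape(xshape)


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (non-overlapping upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator | None = None, name: str = "up"):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_ch), size=(in_ch, out_ch, 2, 2))
        self.weight = Param(w, name=f"{name}.weight")
        self.bias = Param(np.zeros(out_ch), name=f"{name}.bias")
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        y = np.einsum("nchw,cdij->ndhiwj", x, self.weight.value, optimize=True)
        y = y.reshape(n, self.out_ch, 2 * h, 2 * w) + self.bias.value[:, None, None]
        if train:
            self._cache = x
        return y

    def backward(self, grad):
        x = self._cache
        self._cache = None
        n, c, h, w = x.shape
        g6 = grad.reshape(n, self.out_ch, h, 2, w, 2)
        self.weight.grad += np.einsum("nchw,ndhiwj->cdij", x, g6, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        return np.einsum("ndhiwj,cdij->nchw", g6, self.weight.value, optimize=True)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(n_ch), name=f"{name}.gamma")
        self.beta = Param(np.zeros(n_ch), name=f"{name}.beta")
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, grad):
        xhat, inv = self._cache
        self._cache = None
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[:, None, None]
        gm = g.mean(axis=(0, 2, 3))
        gxm = (g * xhat).mean(axis=(0, 2, 3))
        dx = inv[:, None, None] * (g - gm[:, None, None] - xhat * gxm[:, None, None])
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, grad):
        mask = self._mask
        self._mask = None
        return grad * mask


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; gradient routes to a single argmax per window."""

    def __init__(self):
        self._cache = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, grad):
        idx, xshape = self._cache
        self._cache = None
        n, c, h, w = xshape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(xshape)


class AvgPool2d(Layer):
    """2x2 stride-2 average pooling."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if train:
            self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        shape = self._shape
        self._shape = None
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) * 0.25
        return g.reshape(shape)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        mask = self._mask
        self._mask = None
        return grad * mask


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None, name: str = "fc"):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.weight = Param(w, name=f"{name}.weight")
        self.bias = Param(np.zeros(n_out), name=f"{name}.bias")
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        if train:
            self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        x = self._cache
        self._cache = None
        self.weight.grad += grad.T @ x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        shape = self._shape
        self._shape = None
        return grad.reshape(shape)


class GlobalAvgPool2d(Layer):
    """Mean over the spatial axes: (N,C,H,W) -> (N,C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        self._shape = None
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
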