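"""Layers with explicit forward/backward passes.

Conventions
-----------
* ``backward`` *accumulates* parameter gradients into ``self.grads`` (call
  ``zero_grad`` between optimizer steps); this lets a loss touch several
  forward passes of the same network, as the Wasserstein critic loss does.
* Image tensors are NCHW ``float`` arrays.
* Each layer keeps its learnable arrays in ``self.params`` (dict name->array)
  and, after ``backward``, the matching gradients in ``self.grads``.
* ``backward(gy)`` consumes the gradient w.r.t. the layer output and returns
  the gradient w.r.t. the layer input, using caches from the last ``forward``.
* ``training`` toggles batch-norm statistics and dropout.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Extract sliding kxk patches: (N,C,H,W) -> (N,C,kh,kw,oh,ow) view-copy."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = x.shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    if oh <= 0 or ow <= 0:
        raise ValueError(f"kernel {kh}x{kw} stride {stride} too large for input {hp}x{wp}")
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s[0], s[1], s[2], s[3], s[2] * stride, s[3] * stride),
    )
    return np.ascontiguousarray(cols), oh, ow


def _col2im(cols: np.ndarray, x_shape, stride: int, pad: int) -> np.ndarray:
    """Scatter-add patches back: inverse (adjoint) of :func:`_im2col`."""
    n, c, h, w = x_shape
    _, _, kh, kw, oh, ow = cols.shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - abstract
        raise NotImplementedError

    def zero_grad(self):
        self.grads = {}


class Conv2d(Layer):
    """Strided 2-D convolution (cross-correlation), weight (out, in, k, k)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, *, rng=None, w_std=None, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        std = w_std if w_std is not None else np.sqrt(2.0 / fan_in)  # He init
        self.params["w"] = rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def out_size(self, h: int) -> int:
        return (h + 2 * self.pad - self.kernel) // self.stride + 1

    def forward(self, x):
        n = x.shape[0]
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        k = self.in_ch * self.kernel * self.kernel
        colsm = cols.reshape(n, k, oh * ow)
        wm = self.params["w"].reshape(self.out_ch, k)
        y = np.matmul(wm, colsm) + self.params["b"][:, None]
        self._cache = (x.shape, colsm)
        return y.reshape(n, self.out_ch, oh, ow)

    def backward(self, gy):
        x_shape, colsm = self._cache
        n, _, oh, ow = gy.shape
        k = self.in_ch * self.kernel * self.kernel
        gym = gy.reshape(n, self.out_ch, oh * ow)
        self.grads["w"] = self.grads.get("w", 0) + np.einsum("nol,nkl->ok", gym, colsm).reshape(self.params["w"].shape)
        self.grads["b"] = self.grads.get("b", 0) + gy.sum(axis=(0, 2, 3))
        wm = self.params["w"].reshape(self.out_ch, k)
        gcols = np.matmul(wm.T, gym).reshape(n, self.in_ch, self.kernel, self.kernel, oh, ow)
        return _col2im(gcols, x_shape, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Fractionally strided convolution; weight (in, out, k, k).

    Output size = (H-1)*stride - 2*pad + kernel + output_padding; with
    kernel 5, stride 2, pad 2, output_padding 1 each layer exactly doubles
    the spatial side (the DCGAN upsampling convention).
    """

    def __init__(self, in_ch, out_ch, kernel, stride=2, pad=2, output_padding=1, *, rng=None, w_std=0.02, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad, self.opad = kernel, stride, pad, output_padding
        rng = rng or np.random.default_rng(0)
        self.params["w"] = rng.normal(0.0, w_std, (in_ch, out_ch, kernel, kernel)).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.kernel + self.opad

    def forward(self, x):
        n, _, h, w = x.shape
        oh, ow = self.out_size(h), self.out_size(w)
        k = self.kernel
        wm = self.params["w"].reshape(self.in_ch, self.out_ch * k * k)
        xm = x.reshape(n, self.in_ch, h * w)
        cols = np.matmul(wm.T, xm).reshape(n, self.out_ch, k, k, h, w)
        buf = np.zeros((n, self.out_ch, oh + 2 * self.pad, ow + 2 * self.pad), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                buf[:, :, i : i + self.stride * h : self.stride, j : j + self.stride * w : self.stride] += cols[:, :, i, j]
        y = buf[:, :, self.pad : self.pad + oh, self.pad : self.pad + ow]
        y = y + self.params["b"][None, :, None, None]
        self._cache = (xm, x.shape)
        return y

    def backward(self, gy):
        xm, x_shape = self._cache
        n, _, h, w = x_shape
        k = self.kernel
        gbuf = np.pad(gy, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        gcols = np.empty((n, self.out_ch, k, k, h, w), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                gcols[:, :, i, j] = gbuf[:, :, i : i + self.stride * h : self.stride, j : j + self.stride * w : self.stride]
        gcolsm = gcols.reshape(n, self.out_ch * k * k, h * w)
        wm = self.params["w"].reshape(self.in_ch, self.out_ch * k * k)
        self.grads["w"] = self.grads.get("w", 0) + np.einsum("nil,nkl->ik", xm, gcolsm).reshape(self.params["w"].shape)
        self.grads["b"] = self.grads.get("b", 0) + gy.sum(axis=(0, 2, 3))
        dx = np.matmul(wm, gcolsm)
        return dx.reshape(x_shape)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, ch, eps=1e-5, momentum=0.9, dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(ch, dtype=dtype)
        self.params["beta"] = np.zeros(ch, dtype=dtype)
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        self._cache = (xhat, std)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, gy):
        xhat, std = self._cache
        self.grads["gamma"] = self.grads.get("gamma", 0) + (gy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = self.grads.get("beta", 0) + gy.sum(axis=(0, 2, 3))
        gxh = gy * self.params["gamma"][None, :, None, None]
        if not self.training:
            return gxh / std[None, :, None, None]
        mu_g = gxh.mean(axis=(0, 2, 3), keepdims=True)
        mu_gx = (gxh * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (gxh - mu_g - xhat * mu_gx) / std[None, :, None, None]


class Linear(Layer):
    def __init__(self, in_f, out_f, *, rng=None, w_std=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = w_std if w_std is not None else np.sqrt(2.0 / in_f)
        self.params["w"] = rng.normal(0.0, std, (out_f, in_f)).astype(dtype)
        self.params["b"] = np.zeros(out_f, dtype=dtype)

    def forward(self, x):
        self._cache = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, gy):
        x = self._cache
        self.grads["w"] = self.grads.get("w", 0) + gy.T @ x
        self.grads["b"] = self.grads.get("b", 0) + gy.sum(axis=0)
        return gy @ self.params["w"]


class MaxPool2d(Layer):
    def __init__(self, kernel, stride):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def out_size(self, h: int) -> int:
        return (h - self.kernel) // self.stride + 1

    def forward(self, x):
        n, c, h, w = x.shape
        cols, oh, ow = _im2col(x.reshape(n * c, 1, h, w), self.kernel, self.kernel, self.stride, 0)
        colsm = cols.reshape(n * c, self.kernel * self.kernel, oh * ow)
        self._argmax = colsm.argmax(axis=1)
        self._cache = (x.shape, oh, ow)
        y = np.take_along_axis(colsm, self._argmax[:, None, :], axis=1)[:, 0, :]
        return y.reshape(n, c, oh, ow)

    def backward(self, gy):
        x_shape, oh, ow = self._cache
        n, c, h, w = x_shape
        gcolsm = np.zeros((n * c, self.kernel * self.kernel, oh * ow), dtype=gy.dtype)
        np.put_along_axis(gcolsm, self._argmax[:, None, :], gy.reshape(n * c, 1, oh * ow), axis=1)
        gcols = gcolsm.reshape(n * c, 1, self.kernel, self.kernel, oh, ow)
        return _col2im(gcols, (n * c, 1, h, w), self.stride, 0).reshape(x_shape)


class Dropout(Layer):
    """Inverted dropout; `rng` must be set (by the owning model) before training."""

    def __init__(self, p=0.5, rng=None):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without an rng")
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy):
        return gy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape):
        super().__init__()
        self.shape = shape  # per-sample shape

    def forward(self, x):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape))

    def backward(self, gy):
        return gy.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, gy):
        return np.where(self._mask, gy, self.alpha * gy)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, gy):
        return gy * (1.0 - self._y**2)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def set_training(self, flag: bool):
        self.training = flag
        for layer in self.layers:
            if isinstance(layer, Sequential):
                layer.set_training(flag)
            else:
                layer.training = flag

    def parameters(self):
        """Yield (layer, name, array) for every learnable parameter."""
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.parameters()
            else:
                for name in layer.params:
                    yield layer, name, layer.params[name]

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def clip_params(self, c: float):
        """Clip every learnable parameter into [-c, c] in place."""
        for _, _, p in self.parameters():
            np.clip(p, -c, c, out=p)

    def max_abs_param(self) -> float:
        return max(float(np.abs(p).max()) for _, _, p in self.parameters())

    def state_dict(self):
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                state[f"{i}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
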