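"""SGD with momentum and RMSprop over a Sequential's parameters."""

from __future__ import annotations

import numpy as np


class SGD:
    def __init__(self, model, lr: float, momentum: float = 0.0):
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self):
        for layer, name, p in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            if self.momentum:
                key = (id(layer), name)
                v = self._v.get(key)
                if v is None:
                    v = np.zeros_like(p)
                v = self.momentum * v + g
                self._v[key] = v
                p -= (self.lr * v).astype(p.dtype)
            else:
                p -= (self.lr * g).astype(p.dtype)


class RMSprop:
    """RMSprop with EMA of squared gradients (alpha=0.99, eps=1e-8)."""

    def __init__(self, model, lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self._sq: dict[tuple[int, str], np.ndarray] = {}

    def step(self):
        for layer, name, p in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = (id(layer), name)
            s = self._sq.get(key)
            if s is None:
                s = np.zeros_like(p, dtype=np.float64)
            s = self.alpha * s + (1 - self.alpha) * (g.astype(np.float64) ** 2)
            self._sq[key] = s
            p -= (self.lr * g / (np.sqrt(s) + self.eps)).astype(p.dtype)
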