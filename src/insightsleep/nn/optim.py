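"""RMSprop and Adam with the usual default hyperparameters."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, params, lr: float):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):  # pragma: no cover - interface
        raise NotImplementedError


class RMSprop(Optimizer):
    def __init__(self, params, lr=1e-3, alpha=0.99, eps=1e-8):
        super().__init__(params, lr)
        self.alpha = alpha
        self.eps = eps
        self._sq = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]

    def step(self):
        for p, sq in zip(self.params, self._sq):
            g = p.grad.astype(np.float64)
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.value -= (self.lr * g / (np.sqrt(sq) + self.eps)).astype(p.value.dtype)


class Adam(Optimizer):
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        super().__init__(params, lr)
        self.betas = betas
        self.eps = eps
        self._m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self._t = 0

    def step(self):
        b1, b2 = self.betas
        self._t += 1
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(
                p.value.dtype
            )


def make_optimizer(name: str, params, lr: float) -> Optimizer:
    name = name.lower()
    if name == "rmsprop":
        return RMSprop(params, lr=lr)
    if name == "adam":
        return Adam(params, lr=lr)
    raise ValueError(f"unknown optimizer {name!r} (expected 'rmsprop' or 'adam')")
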