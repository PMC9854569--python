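"""Stochastic gradient descent with classical momentum and weight decay."""

from __future__ import annotations

import numpy as np

from spcnet.nn.layers import ParamStore

__all__ = ["SGD"]


class SGD:
    """v <- momentum*v + (grad + wd*w); w <- w - lr*v."""

    def __init__(self, store: ParamStore, lr: float = 1e-3, momentum: float = 0.99,
                 weight_decay: float = 1e-8):
        self.store = store
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = {k: np.zeros_like(t.data) for k, t in store.items()}

    def step(self) -> None:
        for name, t in self.store.items():
            if t.grad is None:
                continue
            g = t.grad
            if self.weight_decay:
                g = g + self.weight_decay * t.data
            v = self._velocity[name]
            v *= self.momentum
            v += g
            t.data = t.data - self.lr * v

    def zero_grad(self) -> None:
        self.store.zero_grad()
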