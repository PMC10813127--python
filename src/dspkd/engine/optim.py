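"""Stochastic gradient descent with classical momentum and weight decay."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class SGD:
    """v <- mu * v - lr * (g + wd * w);  w <- w + v."""

    def __init__(self, params: list[Parameter], lr: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)

    def step(self) -> None:
        lr = np.float32(self.lr)
        mu = np.float32(self.momentum)
        wd = np.float32(self.weight_decay)
        for p in self.params:
            g = p.grad
            if self.weight_decay:
                g = g + wd * p.value
            p.momentum[...] = mu * p.momentum - lr * g
            p.value += p.momentum

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
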