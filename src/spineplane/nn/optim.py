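"""Optimizers for the numpy layer stack."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr=1e-5, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        self.params = list(params)
        self.lr, self.eps, self.weight_decay = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    """Mini-batch gradient descent with (Nesterov-free) momentum."""

    def __init__(self, params, lr=1e-2, momentum=0.99, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.buf = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for p, b in zip(self.params, self.buf):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            b *= self.momentum
            b += g
            p.value -= self.lr * b

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
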