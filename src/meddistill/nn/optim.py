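"""Adam optimizer over Param lists."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam with the standard moment defaults (beta1=0.9, beta2=0.999).

    The learning rate is supplied per step so a multi-step schedule can be
    applied externally without mutating optimizer state.
    """

    def __init__(self, params: list[Param], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for p in params if p.trainable]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
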