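"""Adam optimizer operating in place on (name, value, grad) parameter triples."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {name: np.zeros_like(v) for name, v, _ in params}
        self.v = {name: np.zeros_like(v) for name, v, _ in params}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for name, value, grad in self.params:
            m = self.m[name]
            v = self.v[name]
            m[...] = b1 * m + (1 - b1) * grad
            v[...] = b2 * v + (1 - b2) * grad * grad
            value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
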