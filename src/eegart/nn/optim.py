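"""Adam optimiser (Kingma & Ba) for tape parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr=2e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not (0 < beta1 < 1 and 0 < beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g * g)
            update = (m / b1c) / (np.sqrt(v / b2c) + self.eps)
            p.data = p.data - np.asarray(self.lr * update, dtype=p.data.dtype)
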