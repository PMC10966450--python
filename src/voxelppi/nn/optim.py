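"""Adam optimizer with decoupled weight decay (AdamW)."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adaptive-moment optimizer; weight decay is decoupled from the
    gradient (applied directly to the weights), honouring a regularization
    strategy of "weight decay" rather than L2-in-loss."""

    def __init__(self, params, lr: float = 1e-5, weight_decay: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
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
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * update
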