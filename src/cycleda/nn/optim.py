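"""Adam optimizer for Parameter collections."""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam with bias correction.

    ``params`` is a name -> Parameter mapping (as returned by
    ``Module.parameters``); only those parameters are ever updated, which is
    how the trainer enforces per-phase parameter isolation.
    """

    def __init__(self, params: dict, lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.99, eps: float = 1e-8):
        self.params = dict(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / c1
            vhat = self.v[k] / c2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def state_dict(self) -> dict:
        d = {"t": self.t}
        for k in self.params:
            d[f"m:{k}"] = self.m[k].copy()
            d[f"v:{k}"] = self.v[k].copy()
        return d

    def load_state_dict(self, d: dict):
        self.t = int(d["t"])
        for k in self.params:
            self.m[k][...] = d[f"m:{k}"]
            self.v[k][...] = d[f"v:{k}"]
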