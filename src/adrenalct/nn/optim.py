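"""Adam optimizer over the layer parameter dictionaries."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, named_params, lr=3e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        # named_params: iterable of (name, params_dict, grads_dict)
        self.slots = list(named_params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for name, params, _ in self.slots:
            for key, arr in params.items():
                self.m[(name, key)] = np.zeros_like(arr)
                self.v[(name, key)] = np.zeros_like(arr)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, params, grads in self.slots:
            for key, arr in params.items():
                g = grads[key]
                m = self.m[(name, key)]
                v = self.v[(name, key)]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                arr -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self):
        for _, _, grads in self.slots:
            for key in grads:
                grads[key][...] = 0.0
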