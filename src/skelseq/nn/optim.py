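"""AdamW: Adam with decoupled weight decay.

Decay is applied directly to the parameter (not through the gradient), as
in the transformer fine-tuning literature; callers typically exclude
biases and layer-norm parameters via ``no_decay``.
"""

from __future__ import annotations

import numpy as np

from skelseq.nn.layers import Parameter


class AdamW:
    def __init__(
        self,
        named_params: list[tuple[str, Parameter]],
        lr: float = 2e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
        no_decay: tuple[str, ...] = ("bias", "ln", "gamma", "beta"),
    ):
        self.params = [p for _, p in named_params]
        self.decay_mask = [
            not any(tag in name.lower() for tag in no_decay) for name, _ in named_params
        ]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v, decay in zip(self.params, self.m, self.v, self.decay_mask):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if decay and self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update
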