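"""AdamW with per-group learning rates."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW"]


class AdamW:
    """Decoupled weight-decay Adam.

    ``groups`` maps a group name to ``(params, lr_scale)`` or
    ``(params, lr_scale, wd_scale)`` where ``params`` is a dict of named
    tensors, ``lr_scale`` multiplies the base learning rate passed to
    :meth:`step`, and ``wd_scale`` multiplies the weight decay (0 for
    norm gains, biases and tokens, following ViT convention).
    Differential fine-tuning rates (head vs transformer backbone) are
    expressed through ``lr_scale``.
    """

    def __init__(
        self,
        groups: dict[str, tuple[dict[str, Tensor], float]],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.05,
    ):
        self.groups = groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[tuple[str, str], np.ndarray] = {}
        self._v: dict[tuple[str, str], np.ndarray] = {}

    def step(self, base_lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for gname, group in self.groups.items():
            params, scale = group[0], group[1]
            wd = self.weight_decay * (group[2] if len(group) > 2 else 1.0)
            lr = base_lr * scale
            for pname, p in params.items():
                if p.grad is None:
                    continue
                key = (gname, pname)
                m = self._m.setdefault(key, np.zeros_like(p.data))
                v = self._v.setdefault(key, np.zeros_like(p.data))
                m *= b1
                m += (1.0 - b1) * p.grad
                v *= b2
                v += (1.0 - b2) * p.grad**2
                update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
                p.data -= lr * (update + wd * p.data)

    def zero_grad(self) -> None:
        for group in self.groups.values():
            for p in group[0].values():
                p.grad = None
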