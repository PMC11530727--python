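"""Optimizers for the autodiff parameters."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["SGD"]


class SGD:
    """Stochastic gradient descent with (optional) Nesterov momentum.

    Parameters are passed as groups, each a dict with keys ``params``
    (list of Parameter) and optionally ``weight_decay`` and ``lr_scale``.
    Weight decay is classic L2 (added to the gradient before the momentum
    update), so it can be switched off per group — e.g. for log-variance
    uncertainty parameters, which should not be shrunk toward zero.
    ``lr_scale`` multiplies the global learning rate for that group; it is
    used to frequency-compensate per-participant parameters that receive
    only a fraction of the batches.
    """

    def __init__(self, param_groups, lr: float, momentum: float = 0.9,
                 nesterov: bool = True, weight_decay: float = 0.0):
        if isinstance(param_groups, list) and param_groups and isinstance(param_groups[0], Parameter):
            param_groups = [{"params": param_groups}]
        self.groups = []
        for group in param_groups:
            self.groups.append({
                "params": list(group["params"]),
                "weight_decay": float(group.get("weight_decay", weight_decay)),
                "lr_scale": float(group.get("lr_scale", 1.0)),
            })
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.nesterov = bool(nesterov)
        self._velocity: dict[int, np.ndarray] = {}

    def zero_grad(self):
        for group in self.groups:
            for p in group["params"]:
                p.zero_grad()

    def step(self):
        for group in self.groups:
            wd = group["weight_decay"]
            lr = self.lr * group["lr_scale"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                g = p.grad
                if wd:
                    g = g + wd * p.data
                buf = self._velocity.get(id(p))
                if buf is None:
                    buf = np.array(g, dtype=np.float64)
                    self._velocity[id(p)] = buf
                else:
                    buf *= self.momentum
                    buf += g
                step = g + self.momentum * buf if self.nesterov else buf
                p.data = p.data - lr * step
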