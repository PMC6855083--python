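"""Adam optimizer with a staircase learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Layer


def staircase_lr(step: int, initial_lr: float, decay_rate: float, decay_step: int) -> float:
    """Learning rate after ``step`` optimizer steps: the initial rate
    multiplied by ``decay_rate`` once per completed ``decay_step`` steps."""
    if step < 0:
        raise ValueError("step must be non-negative")
    return initial_lr * decay_rate ** (step // decay_step)


class Adam:
    """Adam over the parameters of a set of layers.

    Standard first/second-moment estimates with bias correction
    (beta1=0.9, beta2=0.999, eps=1e-8).  The learning rate is passed per
    step so any schedule can drive it.
    """

    def __init__(self, layers: list[Layer], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.entries = [(layer, name) for layer in layers for name in layer.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.entries]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.entries]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, (layer, name) in enumerate(self.entries):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1c
            vhat = self.v[k] / b2c
            layer.params[name] -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[name].dtype
            )
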