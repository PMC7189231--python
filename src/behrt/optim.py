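"""AdamW with linear warmup / linear decay, and global-norm clipping."""
from __future__ import annotations

import numpy as np


def linear_warmup_decay(step: int, total_steps: int, warmup_frac: float = 0.1) -> float:
    """Learning-rate multiplier: linear 0->1 over the warmup portion,
    then linear decay to 0 at ``total_steps``."""
    warmup = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup:
        return (step + 1) / warmup
    if total_steps <= warmup:
        return 1.0
    return max(0.0, (total_steps - step) / (total_steps - warmup))


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm <= max_norm."""
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total


class AdamW:
    """Decoupled-weight-decay adaptive-moment optimizer.

    Biases and layer-norm parameters are exempt from weight decay,
    following common transformer practice.
    """

    NO_DECAY_SUFFIXES = (".b", ".beta", ".gamma")

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def _decays(self, name: str) -> bool:
        return not name.endswith(self.NO_DECAY_SUFFIXES)

    def step(self, grads: dict[str, np.ndarray], lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, p in self.params.items():
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and self._decays(name):
                update = update + self.weight_decay * p
            p -= lr * update
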