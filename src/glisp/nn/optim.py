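"""Adam optimizer over a :class:`~glisp.nn.layers.Sequential` or a raw param dict."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            if self.weight_decay:
                g = g + self.weight_decay * p
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_loss_and_grad(logits: np.ndarray, targets: np.ndarray,
                      weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Numerically stable binary cross-entropy on logits.

    Returns (mean weighted loss, gradient w.r.t. logits). ``weights`` are
    per-sample (e.g. inverse class prevalence).
    """
    z = logits.ravel().astype(np.float64)
    y = targets.ravel().astype(np.float64)
    w = np.ones_like(y) if weights is None else weights.ravel().astype(np.float64)
    # log(1 + e^{-|z|}) form avoids overflow for large |z|
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-np.abs(z)))
    p = np.where(z >= 0, p, 1.0 - p)  # sigmoid(z)
    grad = (p - y) * w / len(z)
    return float((loss * w).mean()), grad.reshape(logits.shape).astype(np.float32)
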