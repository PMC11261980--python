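"""A compact feed-forward network in NumPy.

Dense layers with ELU activations on the hidden layers, inverted dropout,
mean-squared-error loss, and AdamW updates (decoupled weight decay).  Sized
for the small regression problems in this package (a few thousand frames,
input widths in the tens); everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np


def elu(z: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    return np.where(z > 0, z, alpha * np.expm1(np.minimum(z, 0.0)))


def elu_grad(z: np.ndarray, a: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    # a = elu(z); derivative is 1 for z>0, a + alpha otherwise
    return np.where(z > 0, 1.0, a + alpha)


class MLP:
    """Multi-layer perceptron: linear layers, ELU on all but the last."""

    def __init__(self, layer_sizes: list[int], seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(scale * rng.standard_normal((fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(
        self,
        X: np.ndarray,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Forward pass; with dropout > 0 applies inverted dropout to the
        input and each hidden activation (training mode)."""
        cache = {"h": [], "z": [], "masks": []}
        h = X
        for k in range(self.n_layers):
            if dropout > 0.0:
                mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * mask
                cache["masks"].append(mask)
            else:
                cache["masks"].append(None)
            cache["h"].append(h)
            z = h @ self.W[k] + self.b[k]
            cache["z"].append(z)
            h = elu(z) if k < self.n_layers - 1 else z
        cache["out"] = h
        return h, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(X)
        return out

    def backward(self, cache, dY: np.ndarray):
        """Gradients of a scalar loss with upstream gradient dY on the output."""
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        delta = dY
        for k in reversed(range(self.n_layers)):
            if k < self.n_layers - 1:
                a = elu(cache["z"][k])
                delta = delta * elu_grad(cache["z"][k], a)
            gW[k] = cache["h"][k].T @ delta
            gb[k] = delta.sum(axis=0)
            delta = delta @ self.W[k].T
            if cache["masks"][k] is not None:
                delta = delta * cache["masks"][k]
        return gW, gb

    def adamw_step(
        self,
        gW,
        gb,
        lr: float = 1e-3,
        weight_decay: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        grads = list(gW) + list(gb)
        decays = [weight_decay] * len(self.W) + [0.0] * len(self.b)
        for i, (w, g, wd) in enumerate(zip(params, grads, decays)):
            m = self._adam_m[i] = 0.9 * self._adam_m[i] + (1 - beta1) * g
            v = self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            w -= lr * (mhat / (np.sqrt(vhat) + eps) + wd * w)

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, W, b) -> None:
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]
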