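"""Minimal feed-forward network core: MLPs, Adam, cosine warm restarts.

Implements exactly the pieces the pretraining and multitask models need —
fully connected layers with ReLU, inverted dropout, He initialisation,
analytic backprop, Adam with decoupled weight decay and a cosine-annealing
learning-rate schedule with warm restarts.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np


class MLP:
    """Fully connected network with ReLU hidden layers and a linear output.

    ``sizes`` is ``[d_in, h1, ..., d_out]``.  Dropout (inverted scaling) is
    applied after each hidden activation during training only.
    """

    def __init__(
        self,
        sizes: Sequence[int],
        rng: np.random.Generator,
        dropout: float = 0.0,
    ) -> None:
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        self.sizes = list(sizes)
        self.dropout = dropout
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            scale = math.sqrt(2.0 / d_in)  # He init for ReLU
            self.weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self._cache: list[tuple] | None = None

    # -- parameter plumbing -------------------------------------------------

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def set_params(self, params: Sequence[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [np.array(p) for p in params[:n]]
        self.biases = [np.array(p) for p in params[n:]]

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    @property
    def d_in(self) -> int:
        return self.sizes[0]

    @property
    def d_out(self) -> int:
        return self.sizes[-1]

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Forward pass; caches activations for :meth:`backward` iff train."""
        if x.shape[1] != self.d_in:
            raise ValueError(
                f"input has {x.shape[1]} features, model expects {self.d_in}"
            )
        cache: list[tuple] = []
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < last:
                a = np.maximum(z, 0.0)
                mask = None
                if train and self.dropout > 0.0:
                    if rng is None:
                        raise ValueError("dropout needs an rng during training")
                    mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                    a = a * mask
                cache.append((h, z, mask))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        self._cache = cache if train else None
        return h

    def backward(self, grad_out: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backprop through the cached forward pass.

        Returns (grad wrt input, grads aligned with :attr:`params`).
        """
        if self._cache is None:
            raise RuntimeError("backward requires a preceding forward(train=True)")
        grads_w = [np.zeros_like(w) for w in self.weights]
        grads_b = [np.zeros_like(b) for b in self.biases]
        g = grad_out
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            h, z, mask = self._cache[i]
            if i < last:
                if mask is not None:
                    g = g * mask
                g = g * (z > 0.0)
            grads_w[i] = h.T @ g
            grads_b[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        return g, grads_w + grads_b


class Adam:
    """Adam with optional decoupled (AdamW-style) weight decay."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:
                p -= lr * self.weight_decay * p
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_warm_restart_lr(base_lr: float, epoch: int, period: int) -> float:
    """Cosine-annealed learning rate that resets every ``period`` epochs."""
    if period <= 0:
        return base_lr
    frac = (epoch % period) / period
    return 0.5 * base_lr * (1.0 + math.cos(math.pi * frac))


def minibatches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Shuffled index batches covering range(n) once."""
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]
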