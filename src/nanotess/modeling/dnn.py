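"""Feedforward neural-network regressor (NumPy implementation).

Architecture: input -> 512 -> 128 -> 64 -> 1 fully connected layers with
rectified-linear activations, inverted dropout (rate 0.2) after each hidden
layer during training, RMSprop optimization at its standard learning rate
(0.001, decay 0.9), mean-squared-error loss, 300 epochs by default.  All
randomness (initialization, dropout masks, batch shuffling) derives from one
seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import DivergenceError


@dataclass(frozen=True)
class DNNParams:
    hidden: tuple[int, ...] = (512, 128, 64)
    dropout: float = 0.2
    lr: float = 0.001
    rho: float = 0.9           # RMSprop decay
    epsilon: float = 1e-7
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0


class DNNModel:
    """Seeded multilayer perceptron for endpoint regression."""

    def __init__(self, params: DNNParams | None = None):
        self.params = params or DNNParams()
        self.history: list[float] = []

    def _init_weights(self, n_in: int, rng) -> None:
        sizes = [n_in, *self.params.hidden, 1]
        self.W, self.b = [], []
        for a, b in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (a + b))  # Glorot uniform
            self.W.append(rng.uniform(-limit, limit, size=(a, b)))
            self.b.append(np.zeros(b))
        self._cache_w = [np.zeros_like(w) for w in self.W]
        self._cache_b = [np.zeros_like(b) for b in self.b]

    def fit(self, X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray) -> "DNNModel":
        p = self.params
        Xv = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float).reshape(-1, 1)
        # standardize the target; training loss is recorded on this scale
        self._y_mean = float(yv.mean())
        self._y_scale = float(yv.std()) or 1.0
        yv = (yv - self._y_mean) / self._y_scale
        rng = np.random.default_rng(p.seed)
        self._init_weights(Xv.shape[1], rng)
        n = len(Xv)
        self.history = []
        for epoch in range(p.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, p.batch_size):
                batch = order[start : start + p.batch_size]
                loss = self._step(Xv[batch], yv[batch], rng)
                losses.append(loss * len(batch))
            epoch_loss = float(np.sum(losses) / n)
            if not np.isfinite(epoch_loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} (seed {p.seed})"
                )
            self.history.append(epoch_loss)
        return self

    def _step(self, Xb: np.ndarray, yb: np.ndarray, rng) -> float:
        p = self.params
        acts, masks = [Xb], []
        h = Xb
        for li, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            if li < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                mask = (rng.random(h.shape) >= p.dropout) / (1.0 - p.dropout)
                h = h * mask
                masks.append(mask)
            else:
                h = z
            acts.append(h)
        pred = acts[-1]
        err = pred - yb
        loss = float(np.mean(err**2))

        grad = 2.0 * err / len(yb)
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        for li in reversed(range(len(self.W))):
            gW[li] = acts[li].T @ grad
            gb[li] = grad.sum(axis=0)
            if li > 0:
                grad = grad @ self.W[li].T
                grad = grad * masks[li - 1]
                grad[acts[li] <= 0] = 0.0
        for li in range(len(self.W)):
            self._cache_w[li] = p.rho * self._cache_w[li] + (1 - p.rho) * gW[li] ** 2
            self._cache_b[li] = p.rho * self._cache_b[li] + (1 - p.rho) * gb[li] ** 2
            self.W[li] -= p.lr * gW[li] / (np.sqrt(self._cache_w[li]) + p.epsilon)
            self.b[li] -= p.lr * gb[li] / (np.sqrt(self._cache_b[li]) + p.epsilon)
        return loss

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        for li, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            h = np.maximum(z, 0.0) if li < len(self.W) - 1 else z
        return h.ravel() * self._y_scale + self._y_mean
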