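"""Sequential network container, Adam optimizer and training step.

Training pairs the pre-softmax logits with the cross-entropy loss (the
usual numerically stable fusion); inference runs the full stack including
the softmax layer, so predicted probability vectors are non-negative and
sum to one.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence

import numpy as np

from .layers import Layer, Softmax


def _logsumexp(z: np.ndarray) -> np.ndarray:
    m = z.max(axis=-1, keepdims=True)
    return (m + np.log(np.exp(z - m).sum(axis=-1, keepdims=True)))[..., 0]


class Network:
    """An ordered stack of layers ending in a Softmax."""

    def __init__(self, layers: Sequence[Layer]):
        if not layers or not isinstance(layers[-1], Softmax):
            raise ValueError("a network must end in a Softmax layer")
        self.layers = list(layers)

    # -- inference -------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Probabilities in inference mode, batched for memory safety."""
        outs = [self.forward(x[i:i + batch_size], training=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.empty((0, 0))

    # -- training --------------------------------------------------------
    def logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers[:-1]:
            x = layer.forward(x, training=training)
        return x

    def train_step_gradients(self, x: np.ndarray, y: np.ndarray) -> float:
        """Forward + backward on one mini-batch; fills every layer's grads.

        ``y`` holds integer class indices. Returns the mean cross-entropy.
        """
        z = self.logits(x, training=True)
        n = len(x)
        loss = float(np.mean(_logsumexp(z) - z[np.arange(n), y]))
        p = np.exp(z - _logsumexp(z)[:, None])
        dz = p.copy()
        dz[np.arange(n), y] -= 1.0
        dz /= n
        for layer in reversed(self.layers[:-1]):
            dz = layer.backward(dz)
        return loss

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray,
                      batch_size: int = 256) -> float:
        losses = []
        for i in range(0, len(x), batch_size):
            z = self.logits(x[i:i + batch_size], training=False)
            yb = y[i:i + batch_size]
            losses.append(_logsumexp(z) - z[np.arange(len(yb)), yb])
        return float(np.mean(np.concatenate(losses)))

    # -- parameters ------------------------------------------------------
    @property
    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> List[np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        weights = [p.copy() for p in self.params]
        for layer in self.layers:
            if hasattr(layer, "running_mean"):
                weights.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return weights

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for p in self.params:
            p[...] = next(it)
        for layer in self.layers:
            if hasattr(layer, "running_mean"):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)
        try:
            next(it)
        except StopIteration:
            return
        raise ValueError("too many weight arrays")


class Adam:
    """Adam with a per-step learning-rate schedule."""

    def __init__(self, params: Sequence[np.ndarray],
                 lr_fn: Callable[[int], float],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr_fn = lr_fn
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.step_count = 0

    def step(self, grads: Sequence[np.ndarray]) -> float:
        """Apply one update; returns the learning rate used."""
        lr = self.lr_fn(self.step_count)
        self.step_count += 1
        t = self.step_count
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
        return lr
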