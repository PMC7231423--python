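"""Minimal numpy neural-network primitives for the transfer classifiers.

Only what the frozen-backbone design needs: a small random convolutional
feature extractor (never trained), a two-hidden-layer dense head with a
2-way softmax trained by backprop, and the two optimizers used by the
training recipes (SGD with per-update learning-rate decay, Adam).
Everything is deterministic under a numpy Generator seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["glorot_uniform", "softmax", "DenseHead", "SGD", "Adam",
           "TinyConvBackbone"]


def glorot_uniform(rng: np.random.Generator, fan_in: int,
                   fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class TinyConvBackbone:
    """Three 3x3/stride-2 conv+ReLU blocks with fixed random weights.

    Acts as an untrained generic feature extractor so the full pipeline
    runs with no weight download; weights are Glorot-initialized from
    the seed and are never updated (the backbone is frozen by design).
    Input (N, 224, 224, 3) -> features (N, 27, 27, 32).
    """

    channels = (3, 8, 16, 32)

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.kernels = []
        self.biases = []
        for c_in, c_out in zip(self.channels, self.channels[1:]):
            fan = 9 * c_in
            self.kernels.append(
                glorot_uniform(rng, fan, c_out, (fan, c_out)).astype(np.float32)
            )
            self.biases.append(np.zeros(c_out, dtype=np.float32))

    @staticmethod
    def _conv_s2(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        # valid 3x3 convolution, stride 2, via im2col
        patches = sliding_window_view(x, (3, 3), axis=(1, 2))[:, ::2, ::2]
        n, ho, wo = patches.shape[:3]
        cols = patches.reshape(n, ho, wo, -1)
        return np.maximum(cols @ w + b, 0.0)

    def forward(self, images: np.ndarray, batch: int = 16) -> np.ndarray:
        """Feature maps for a batch of (N, 224, 224, 3) images."""
        out = []
        for i in range(0, len(images), batch):
            x = np.asarray(images[i : i + batch], dtype=np.float32)
            for w, b in zip(self.kernels, self.biases):
                x = self._conv_s2(x, w, b)
            out.append(x)
        return np.concatenate(out, axis=0)

    def parameters(self) -> list[np.ndarray]:
        return list(self.kernels) + list(self.biases)

    def parameter_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def feature_shape(self) -> tuple[int, int, int]:
        return (27, 27, self.channels[-1])


class DenseHead:
    """FC1 -> ReLU -> FC2 -> ReLU -> softmax(2), Glorot-initialized."""

    def __init__(self, in_dim: int, fc_sizes: tuple[int, int],
                 n_classes: int = 2, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        dims = (in_dim, *fc_sizes, n_classes)
        self.weights = [glorot_uniform(rng, a, b) for a, b in zip(dims, dims[1:])]
        self.biases = [np.zeros(b) for b in dims[1:]]

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def parameter_count(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, features: np.ndarray):
        """Returns class probabilities and the activation cache."""
        a = np.asarray(features, dtype=np.float64)
        cache = [a]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
            cache.append(a)
        probs = softmax(a @ self.weights[-1] + self.biases[-1])
        return probs, cache

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.forward(features)[0]

    def backward(self, probs: np.ndarray, cache: list[np.ndarray],
                 y_onehot: np.ndarray):
        """Gradients of mean cross-entropy w.r.t. weights and biases."""
        batch = len(y_onehot)
        delta = (probs - y_onehot) / batch
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w[layer] = cache[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (cache[layer] > 0)
        return grads_w + grads_b

    def copy_parameters(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n_w = len(self.weights)
        self.weights = [p.copy() for p in params[:n_w]]
        self.biases = [p.copy() for p in params[n_w:]]


class SGD:
    """Gradient descent with the classic per-update multiplicative decay:
    lr_t = lr0 / (1 + decay * t)."""

    def __init__(self, lr: float = 1e-3, decay: float = 1e-5):
        self.lr0 = lr
        self.decay = decay
        self.iterations = 0
        self.lr_scale = 1.0  # plateau scheduler hook

    @property
    def lr(self) -> float:
        return self.lr_scale * self.lr0 / (1.0 + self.decay * self.iterations)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        lr = self.lr
        for p, g in zip(params, grads):
            p -= lr * g
        self.iterations += 1


class Adam:
    """Adam with bias-corrected first/second moments."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr0 = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.iterations = 0
        self.lr_scale = 1.0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    @property
    def lr(self) -> float:
        return self.lr_scale * self.lr0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.iterations += 1
        t = self.iterations
        lr_t = self.lr * np.sqrt(1 - self.beta2**t) / (1 - self.beta1**t)
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
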