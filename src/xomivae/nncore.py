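"""Minimal feed-forward neural-network core.

Dense layers and elementwise activations with explicit forward/backward
passes on numpy arrays, plus an Adam optimizer. Keeping the network as an
ordered list of primitive layers is what makes activation-level attribution
possible: the rescale rule needs every layer's pre-activation for both the
explained sample and the reference, which is exactly what
:meth:`FeedForward.forward_all` exposes.

Shapes follow the (batch, features) convention throughout; a ``Linear``
stores its weight as ``(n_in, n_out)`` so ``y = x @ W + b``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "ReLU",
    "Sigmoid",
    "Tanh",
    "FeedForward",
    "Adam",
]


class Layer:
    """Base class: a differentiable map with optional parameters."""

    has_params = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Linear(Layer):
    has_params = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng()
        # He-style scaling; works for both ReLU and near-linear regimes used here
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    @classmethod
    def from_weights(cls, W: np.ndarray, b: np.ndarray | None = None) -> "Linear":
        W = np.asarray(W, dtype=float)
        obj = cls.__new__(cls)
        obj.W = W
        obj.b = np.zeros(W.shape[1]) if b is None else np.asarray(b, dtype=float)
        obj.gW = np.zeros_like(obj.W)
        obj.gb = np.zeros_like(obj.b)
        obj._x = None
        return obj

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called before forward")
        self.gW = self._x.T @ grad_out
        self.gb = grad_out.sum(axis=0)
        return grad_out @ self.W.T


class Activation(Layer):
    """Elementwise nonlinearity f; subclasses provide f and f'."""

    def f(self, a: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def fprime(self, a: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._a = x
        return self.f(x)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self.fprime(self._a)


class ReLU(Activation):
    def f(self, a):
        return np.maximum(a, 0.0)

    def fprime(self, a):
        return (a > 0).astype(float)


class Sigmoid(Activation):
    def f(self, a):
        return 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500)))

    def fprime(self, a):
        s = self.f(a)
        return s * (1.0 - s)


class Tanh(Activation):
    def f(self, a):
        return np.tanh(a)

    def fprime(self, a):
        return 1.0 - np.tanh(a) ** 2


class FeedForward:
    """An ordered stack of layers computing a vector-valued function."""

    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    @property
    def n_in(self) -> int:
        for lyr in self.layers:
            if isinstance(lyr, Linear):
                return lyr.W.shape[0]
        raise ValueError("stack has no Linear layer")

    @property
    def n_out(self) -> int:
        for lyr in reversed(self.layers):
            if isinstance(lyr, Linear):
                return lyr.W.shape[1]
        raise ValueError("stack has no Linear layer")

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def forward_all(self, x: np.ndarray) -> list[np.ndarray]:
        """Forward pass returning [input, out_1, ..., out_L] for every layer."""
        acts = [x]
        for lyr in self.layers:
            x = lyr.forward(x)
            acts.append(x)
        return acts

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Backprop a cotangent through the cached forward pass."""
        g = grad_out
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        return g

    def gradient(self, x: np.ndarray, out_index: int) -> np.ndarray:
        """d output[out_index] / d input, rowwise over the batch."""
        out = self.forward(np.atleast_2d(x))
        seed = np.zeros_like(out)
        seed[:, out_index] = 1.0
        return self.backward(seed)

    def param_layers(self) -> list[Linear]:
        return [l for l in self.layers if l.has_params]


def random_feedforward(rng: np.random.Generator, n_in: int, n_out: int = 1,
                       n_hidden_layers: int | None = None,
                       activations: tuple[type, ...] = (ReLU, Sigmoid),
                       width_range: tuple[int, int] = (3, 12),
                       linear_only: bool = False) -> FeedForward:
    """A random small network, for verification of attribution rules."""
    if n_hidden_layers is None:
        n_hidden_layers = int(rng.integers(1, 4))
    widths = [n_in] + [int(rng.integers(*width_range))
                       for _ in range(n_hidden_layers)] + [n_out]
    layers: list[Layer] = []
    for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
        layers.append(Linear(a, b, rng))
        if not linear_only and i < len(widths) - 2:
            layers.append(activations[int(rng.integers(len(activations)))]())
    return FeedForward(layers)


class Adam:
    """Adam over the Linear layers of one or more stacks."""

    def __init__(self, layers: list[Linear], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.layers = [l for l in layers if l.has_params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]
        self._v = [(np.zeros_like(l.W), np.zeros_like(l.b)) for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, lyr in enumerate(self.layers):
            for j, (p, g) in enumerate(((lyr.W, lyr.gW), (lyr.b, lyr.gb))):
                m = self._m[i][j]
                v = self._v[i][j]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and j == 0:  # decoupled decay, W only
                    p -= self.lr * self.weight_decay * p

    def zero_grad(self) -> None:
        for lyr in self.layers:
            lyr.gW[...] = 0.0
            lyr.gb[...] = 0.0
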