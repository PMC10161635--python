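"""Minimal feed-forward networks with explicit backpropagation.

Implements exactly what the dosing agent and the state autoencoder need:
fully connected layers, leaky-ReLU activations, a softmax head, mini-batch
SGD with momentum, soft (Polyak) parameter updates, and a dueling
state-value/advantage head. Everything is plain numpy so a single integer
seed makes whole training runs bit-reproducible on any machine.

Gradient conventions: ``backward`` consumes d(loss)/d(output) for the batch
and returns d(loss)/d(input); parameter gradients are stored on each
``Linear`` (overwritten, not accumulated, per backward pass).
"""

from __future__ import annotations

import copy

import numpy as np

from .errors import ContractError

__all__ = [
    "Linear",
    "LeakyReLU",
    "MLP",
    "MomentumSGD",
    "softmax",
    "softmax_backward",
    "soft_update",
]


class Linear:
    """Affine layer ``y = x W + b`` with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise ContractError("backward called before forward")
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]


class LeakyReLU:
    """Elementwise ``max(x, slope*x)``; slope in (0,1)."""

    def __init__(self, slope: float):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.slope * g)


class MLP:
    """Stack of Linear layers with leaky-ReLU between them.

    ``activate_last`` applies the activation after the final Linear too
    (used for shared trunks feeding separate heads).
    """

    def __init__(
        self,
        sizes: list[int],
        slope: float,
        rng: np.random.Generator,
        activate_last: bool = False,
    ):
        if len(sizes) < 2:
            raise ContractError("MLP needs at least input and output sizes")
        self.layers: list[Linear | LeakyReLU] = []
        n_linear = len(sizes) - 1
        for i in range(n_linear):
            self.layers.append(Linear(sizes[i], sizes[i + 1], rng))
            if i < n_linear - 1 or activate_last:
                self.layers.append(LeakyReLU(slope))

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def linears(self) -> list[Linear]:
        return [l for l in self.layers if isinstance(l, Linear)]

    def parameters(self) -> list[np.ndarray]:
        return [p for l in self.linears() for p in l.params()]


class MomentumSGD:
    """Mini-batch SGD with classical momentum over a set of Linear layers."""

    def __init__(self, linears: list[Linear], lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ContractError("learning rate must be positive")
        self.linears = linears
        self.lr = lr
        self.momentum = momentum
        self._vel = [[np.zeros_like(p) for p in l.params()] for l in linears]

    def step(self) -> None:
        for layer, vels in zip(self.linears, self._vel):
            for p, g, v in zip(layer.params(), layer.grads(), vels):
                v *= self.momentum
                v += g
                p -= self.lr * v


class Adam:
    """Adam optimizer over a set of Linear layers."""

    def __init__(
        self,
        linears: list[Linear],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ContractError("learning rate must be positive")
        self.linears = linears
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [[np.zeros_like(p) for p in l.params()] for l in linears]
        self._v = [[np.zeros_like(p) for p in l.params()] for l in linears]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self._t
        bias2 = 1 - b2**self._t
        for layer, ms, vs in zip(self.linears, self._m, self._v):
            for p, g, m, v in zip(layer.params(), layer.grads(), ms, vs):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def make_optimizer(kind: str, linears: list[Linear], lr: float, momentum: float = 0.9):
    if kind == "sgd":
        return MomentumSGD(linears, lr, momentum)
    if kind == "adam":
        return Adam(linears, lr)
    raise ContractError(f"unknown optimizer {kind!r}")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(probs: np.ndarray, g: np.ndarray) -> np.ndarray:
    """d(loss)/d(logits) given d(loss)/d(probs) and the softmax output."""
    return probs * (g - (g * probs).sum(axis=-1, keepdims=True))


def soft_update(
    online_params: list[np.ndarray], target_params: list[np.ndarray], tau: float
) -> None:
    """Polyak averaging in place: target <- tau*online + (1-tau)*target."""
    if not 0 < tau <= 1:
        raise ContractError(f"tau must lie in (0, 1], got {tau}")
    if len(online_params) != len(target_params):
        raise ContractError("parameter lists differ in length")
    for p, t in zip(online_params, target_params):
        if p.shape != t.shape:
            raise ContractError(f"shape mismatch {p.shape} vs {t.shape}")
        t *= 1.0 - tau
        t += tau * p


def clone_network(net):
    """Deep copy used to initialize target networks equal to online ones."""
    return copy.deepcopy(net)
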