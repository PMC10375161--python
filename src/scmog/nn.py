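"""A compact feed-forward neural-network core on numpy.

Provides exactly what the translator models need: dense layers, leaky-ReLU
and sigmoid activations, reverse-mode gradients, Xavier-uniform
initialisation, and RMSProp/Adam optimisers.  Networks here contain no
batch-coupled layers (no batch norm, no dropout), so a cell's output is
independent of which batch it is computed in — a property the test suite
relies on.

All arithmetic is float64; forward passes cache activations for the
following backward pass, so each ``backward`` must follow its ``forward``.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def xavier_uniform_limit(n_in: int, n_out: int) -> float:
    """Half-width of the Xavier/Glorot uniform range sqrt(6/(fan_in+fan_out))."""
    return float(np.sqrt(6.0 / (n_in + n_out)))


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class Linear:
    """Dense layer y = x W + b with gradient accumulation on backward."""

    def __init__(self, n_in: int, n_out: int):
        self.n_in = n_in
        self.n_out = n_out
        self.W = np.zeros((n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def init_xavier(self, rng: np.random.Generator) -> None:
        limit = xavier_uniform_limit(self.n_in, self.n_out)
        self.W = rng.uniform(-limit, limit, size=(self.n_in, self.n_out))
        self.b = np.zeros(self.n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def parameters(self):
        return [("W", self), ("b", self)]


class LeakyReLU:
    """max(x, slope*x); default negative slope 0.01."""

    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.where(x > 0, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * np.where(self._x > 0, 1.0, self.slope)

    def parameters(self):
        return []


class Sigmoid:
    def __init__(self):
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = expit(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._y * (1.0 - self._y)

    def parameters(self):
        return []


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def linears(self) -> list[Linear]:
        return [l for l in self.layers if isinstance(l, Linear)]


def get_params(net) -> list[np.ndarray]:
    """Flat list of parameter arrays (references, in stable order)."""
    return [getattr(owner, name) for name, owner in net.parameters()]


def get_grads(net) -> list[np.ndarray]:
    return [getattr(owner, "g" + name) for name, owner in net.parameters()]


def get_state(net) -> list[np.ndarray]:
    return [p.copy() for p in get_params(net)]


def set_state(net, state: list[np.ndarray]) -> None:
    slots = net.parameters()
    if len(slots) != len(state):
        raise ValueError("state length mismatch")
    for (name, owner), value in zip(slots, state):
        current = getattr(owner, name)
        if current.shape != value.shape:
            raise ValueError(f"shape mismatch for {name}: {current.shape} vs {value.shape}")
        setattr(owner, name, value.copy())


def n_parameters(net) -> int:
    return int(sum(p.size for p in get_params(net)))


class RMSProp:
    """RMSProp with running squared-gradient average (alpha=0.99)."""

    def __init__(self, net, lr: float = 5e-5, alpha: float = 0.99, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq = [np.zeros_like(p) for p in get_params(net)]

    def step(self) -> None:
        params = self.net.parameters()
        for i, (name, owner) in enumerate(params):
            g = getattr(owner, "g" + name)
            self.sq[i] = self.alpha * self.sq[i] + (1 - self.alpha) * g * g
            update = self.lr * g / (np.sqrt(self.sq[i]) + self.eps)
            setattr(owner, name, getattr(owner, name) - update)


class Adam:
    """Adam with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, net, lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in get_params(net)]
        self.v = [np.zeros_like(p) for p in get_params(net)]

    def step(self) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for i, (name, owner) in enumerate(self.net.parameters()):
            g = getattr(owner, "g" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            update = self.lr * (self.m[i] / b1c) / (np.sqrt(self.v[i] / b2c) + self.eps)
            setattr(owner, name, getattr(owner, name) - update)


class ModuleGroup:
    """Treat several networks as one parameter collection for an optimiser."""

    def __init__(self, *nets):
        self.nets = nets

    def parameters(self):
        out = []
        for net in self.nets:
            out.extend(net.parameters())
        return out


def clip_weights(net, limit: float) -> None:
    """Clamp every parameter into [-limit, limit] in place (WGAN critic clip)."""
    for name, owner in net.parameters():
        np.clip(getattr(owner, name), -limit, limit, out=getattr(owner, name))
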