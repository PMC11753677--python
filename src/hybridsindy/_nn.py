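"""Minimal fully-connected network with analytic reverse-mode gradients.

The networks used here are tiny (one or two hidden layers of 8 units), so a
hand-written numpy implementation is both fast and exactly differentiable.
Hidden layers use a smooth activation (tanh by default) so the network can
be integrated by an ODE solver; the output layer is linear.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


def _tanh(z):
    return np.tanh(z)


def _tanh_deriv(z, a):
    return 1.0 - a * a


def _softplus(z):
    return np.logaddexp(0.0, z)


def _softplus_deriv(z, a):
    return 1.0 / (1.0 + np.exp(-z))


_ACTIVATIONS = {"tanh": (_tanh, _tanh_deriv), "softplus": (_softplus, _softplus_deriv)}


class MLP:
    """Fully-connected network, linear output layer.

    Parameters
    ----------
    sizes : sequence of int
        Layer widths including input and output, e.g. ``[2, 8, 2]``.
    activation : str
        Hidden-layer nonlinearity, ``"tanh"`` (default) or ``"softplus"``.
    seed : int
        Seed for fan-in-scaled uniform weight initialization
        (U(-1/sqrt(fan_in), 1/sqrt(fan_in)) for weights and biases).  The
        output layer starts at exactly zero, so the network is initially
        the zero function: a hybrid model begins as its known part alone.
    """

    def __init__(self, sizes, activation: str = "tanh", seed: int = 0):
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        if any(s < 1 for s in sizes):
            raise ValueError("layer widths must be positive")
        self.sizes = list(sizes)
        self.activation = activation
        self._act, self._act_deriv = _ACTIVATIONS[activation]
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []  # alternating W (in, out) and b (out,)
        n_pairs = len(sizes) - 1
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            bound = 1.0 / np.sqrt(n_in)
            W = rng.uniform(-bound, bound, size=(n_in, n_out))
            b = rng.uniform(-bound, bound, size=n_out)
            if i == n_pairs - 1:
                W = np.zeros_like(W)
                b = np.zeros_like(b)
            self.weights.append(W)
            self.weights.append(b)

    @property
    def n_layers(self) -> int:
        return len(self.sizes) - 1

    def copy_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights]

    def set_weights(self, weights) -> None:
        for own, new in zip(self.weights, weights):
            own[...] = new

    def forward(self, x: np.ndarray, need_cache: bool = False):
        """Evaluate the network on ``x`` of shape ``(..., d_in)``.

        With ``need_cache=True`` also returns the intermediates needed by
        :meth:`backward`.
        """
        x = np.asarray(x, dtype=float)
        lead = x.shape[:-1]
        a = x.reshape(-1, x.shape[-1])
        inputs, preacts = [], []
        L = self.n_layers
        for i in range(L):
            W, b = self.weights[2 * i], self.weights[2 * i + 1]
            inputs.append(a)
            z = a @ W + b
            if i < L - 1:
                a = self._act(z)
                preacts.append(z)
            else:
                a = z
        out = a.reshape(*lead, self.sizes[-1])
        if need_cache:
            return out, (lead, inputs, preacts)
        return out

    def backward(self, cache, v: np.ndarray):
        """Vector-Jacobian product: given dL/d(output) ``v``, return
        ``(dL/d(input), [dL/dW1, dL/db1, ...])``."""
        lead, inputs, preacts = cache
        delta = np.asarray(v, dtype=float).reshape(-1, self.sizes[-1])
        grads: list[np.ndarray | None] = [None] * len(self.weights)
        L = self.n_layers
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                z = preacts[i]
                a = self._act(z)
                delta = delta * self._act_deriv(z, a)
            W = self.weights[2 * i]
            grads[2 * i] = inputs[i].T @ delta
            grads[2 * i + 1] = delta.sum(axis=0)
            delta = delta @ W.T
        return delta.reshape(*lead, self.sizes[0]), grads

    def zero_grads(self) -> list[np.ndarray]:
        return [np.zeros_like(w) for w in self.weights]


class Adam:
    """Adam optimizer operating in-place on a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
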