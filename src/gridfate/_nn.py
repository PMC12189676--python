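"""Minimal two-layer perceptron with manual backprop and Adam.

Just enough network machinery for the actor-critic and double-DQN learners:
a ReLU hidden layer, a linear output layer, gradients computed by hand, and
an Adam step.  Shapes follow the (batch, features) convention throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "softmax", "sigmoid", "smooth_l1"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def smooth_l1(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Huber loss (delta=1) and its derivative, elementwise."""
    a = np.abs(x)
    loss = np.where(a < 1.0, 0.5 * x**2, a - 0.5)
    grad = np.where(a < 1.0, x, np.sign(x))
    return loss, grad


class MLP:
    """x -> W2 @ relu(W1 @ x + b1) + b2."""

    def __init__(self, n_in: int, n_out: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(2.0 / n_in)
        s2 = np.sqrt(2.0 / hidden)
        self.params = {
            "W1": rng.normal(0.0, s1, size=(n_in, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0.0, s2, size=(hidden, n_out)),
            "b2": np.zeros(n_out),
        }

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        x = np.atleast_2d(x)
        p = self.params
        pre = x @ p["W1"] + p["b1"]
        h = np.maximum(pre, 0.0)
        out = h @ p["W2"] + p["b2"]
        if cache is not None:
            cache.update(x=x, pre=pre, h=h)
        return out

    def backward(self, cache: dict, d_out: np.ndarray) -> dict:
        """Gradients of a scalar loss given d(loss)/d(output)."""
        p = self.params
        d_out = np.atleast_2d(d_out)
        grads = {
            "W2": cache["h"].T @ d_out,
            "b2": d_out.sum(axis=0),
        }
        dh = d_out @ p["W2"].T
        dpre = dh * (cache["pre"] > 0)
        grads["W1"] = cache["x"].T @ dpre
        grads["b1"] = dpre.sum(axis=0)
        return grads

    def copy_from(self, other: "MLP", tau: float = 1.0) -> None:
        """Soft-blend parameters: self <- (1 - tau) * self + tau * other."""
        for k in self.params:
            self.params[k] = (1.0 - tau) * self.params[k] + tau * other.params[k]

    def clone(self) -> "MLP":
        out = MLP.__new__(MLP)
        out.params = {k: v.copy() for k, v in self.params.items()}
        return out


class Adam:
    def __init__(self, net: MLP, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in net.params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            self.net.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
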