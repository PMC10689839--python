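"""A small multilayer perceptron for tabular binary classification.

Architecture: a stack of linear layers with rectifier activations and dropout
(probability 0.5 by default) on every hidden layer, ending in a single logit mapped
through a sigmoid to the positive-class probability.  Gradients are derived by hand
because the reshaped loss differentiates through a modified probability
(``d loss / d p`` changes per sample when a boost is active), which rules out any
fixed library loss; everything else is ordinary dense backpropagation.

Optimisers: Adam and plain SGD, both with decoupled L2 weight decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLPSpec", "MLP", "AdamState", "make_optimizer"]


@dataclass(frozen=True)
class MLPSpec:
    """Widths of the hidden layers plus the dropout probability."""

    hidden: tuple[int, ...] = (32, 16)
    dropout: float = 0.5


class MLP:
    """Dense network with ReLU + dropout hidden layers and a sigmoid output."""

    def __init__(self, n_features: int, spec: MLPSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        widths = [n_features, *spec.hidden, 1]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(widths, widths[1:])
        ]
        self.b = [np.zeros(w) for w in widths[1:]]

    # -- forward ------------------------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """Positive-class probabilities; dropout is active only when training."""
        p, _ = self._forward_cached(X, train)
        return p

    def _forward_cached(self, X: np.ndarray, train: bool):
        cache = {"a": [X], "mask": []}
        h = X
        n_hidden = len(self.W) - 1
        for i in range(n_hidden):
            z = h @ self.W[i] + self.b[i]
            h = np.maximum(z, 0.0)
            if train and self.spec.dropout > 0.0:
                keep = 1.0 - self.spec.dropout
                mask = (self.rng.random(h.shape) < keep) / keep
                h = h * mask
            else:
                mask = None
            cache["a"].append(h)
            cache["mask"].append(mask)
        logit = np.clip((h @ self.W[-1] + self.b[-1]).ravel(), -500.0, 500.0)
        p = 1.0 / (1.0 + np.exp(-logit))
        return p, cache

    # -- backward -----------------------------------------------------------------

    def backward(self, X: np.ndarray, dloss_dp_fn, train: bool = True):
        """Gradients of a scalar loss given a rule for per-sample d loss / d p.

        ``dloss_dp_fn(p)`` receives the probabilities of this forward pass (fresh
        dropout masks when training) and returns the per-sample derivative of the
        loss with respect to them; ``dloss_dp * p * (1 - p)`` is then
        backpropagated through the stack.  Returns ``(p, grads_W, grads_b)``.
        """
        p, cache = self._forward_cached(X, train)
        dloss_dp = np.asarray(dloss_dp_fn(p), dtype=float)
        delta = (dloss_dp * p * (1.0 - p))[:, None]  # d loss / d logit
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        grads_W[-1] = cache["a"][-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        back = delta @ self.W[-1].T
        for i in range(len(self.W) - 2, -1, -1):
            h = cache["a"][i + 1]
            mask = cache["mask"][i]
            if mask is not None:
                back = back * mask
            back = back * (h > 0.0 if mask is None else (h != 0.0))
            grads_W[i] = cache["a"][i].T @ back
            grads_b[i] = back.sum(axis=0)
            if i > 0:
                back = back @ self.W[i].T
        return p, grads_W, grads_b

    @property
    def params(self):
        return self.W + self.b

    def get_state(self) -> list[np.ndarray]:
        return [w.copy() for w in self.W] + [b.copy() for b in self.b]

    def set_state(self, state: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [w.copy() for w in state[:k]]
        self.b = [b.copy() for b in state[k:]]


@dataclass
class AdamState:
    lr: float
    weight_decay: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)

    def step(self, model: MLP, grads_W, grads_b) -> None:
        grads = grads_W + grads_b
        params = model.W + model.b
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            g = g + self.weight_decay * p
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class SGDState:
    lr: float
    weight_decay: float

    def step(self, model: MLP, grads_W, grads_b) -> None:
        for p, g in zip(model.W + model.b, grads_W + grads_b):
            p -= self.lr * (g + self.weight_decay * p)


def make_optimizer(name: str, lr: float, weight_decay: float):
    if name == "adam":
        return AdamState(lr=lr, weight_decay=weight_decay)
    if name == "sgd":
        return SGDState(lr=lr, weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}")
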