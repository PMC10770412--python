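"""Minimal NumPy feed-forward building blocks with analytic gradients.

The networks in this package are small (a few hundred units), so layers are
implemented directly: each layer caches its forward pass and implements an
exact backward pass. Correctness is guarded by finite-difference gradient
tests. Everything runs in float64; randomness always flows through an
explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "MaskedLinear", "BatchNorm", "ReLU", "Tanh", "Sigmoid", "Dropout", "Adam"]


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Linear:
    """Affine map x @ W + b. Set ``bias=False`` for a bias-free output layer."""

    def __init__(self, n_in, n_out, rng, bias=True):
        self.W = glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out) if bias else None

    def forward(self, x, training=False):
        self._x = x
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def backward(self, grad):
        self.dW = self._x.T @ grad
        if self.b is not None:
            self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [("W", self)] + ([("b", self)] if self.b is not None else [])


class MaskedLinear(Linear):
    """Linear layer whose weight support is restricted to a binary mask.

    Forbidden entries are zeroed at initialization, in every gradient, and
    (defensively) after every optimizer step via :meth:`project`.
    """

    def __init__(self, mask, rng, bias=True):
        mask = np.asarray(mask, dtype=float)
        super().__init__(mask.shape[0], mask.shape[1], rng, bias=bias)
        self.mask = mask
        self.W *= mask

    def backward(self, grad):
        out = super().backward(grad)
        self.dW *= self.mask
        return out

    def project(self):
        self.W *= self.mask


class BatchNorm:
    """Batch normalization with running statistics for inference mode.

    Uses the biased batch variance both for normalization and for the
    running estimate (momentum 0.1); in inference mode the layer is a fixed
    elementwise affine map, which is what attribution folding relies on.
    """

    def __init__(self, n, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        xhat = self._xhat
        self.dgamma = (grad * xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        g = grad * self.gamma / self._std
        if not self._training:
            return g
        return g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)

    def inference_affine(self):
        """Return (a, c) with eval-mode output == a * x + c, elementwise."""
        a = self.gamma / np.sqrt(self.running_var + self.eps)
        c = self.beta - a * self.running_mean
        return a, c

    def params(self):
        return [("gamma", self), ("beta", self)]


class ReLU:
    def forward(self, x, training=False):
        self._m = x > 0
        return x * self._m

    def backward(self, grad):
        return grad * self._m


class Tanh:
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1 - self._y**2)


class Sigmoid:
    def forward(self, x, training=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1 - self._y)


class Dropout:
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0:
            self._m = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._m = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._m

    def backward(self, grad):
        return grad if self._m is None else grad * self._m


class Adam:
    """Adam over a list of (attribute-name, layer) parameter handles.

    Gradients are read from ``layer.d<name>``; masked layers are re-projected
    after each step so the forbidden zero pattern survives training exactly.
    """

    def __init__(self, handles, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.handles = list(handles)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(layer, name)) for name, layer in self.handles]
        self.v = [np.zeros_like(getattr(layer, name)) for name, layer in self.handles]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (name, layer) in enumerate(self.handles):
            g = getattr(layer, "d" + name)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p = getattr(layer, name)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        for _, layer in self.handles:
            if isinstance(layer, MaskedLinear):
                layer.project()
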