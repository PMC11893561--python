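"""Small neural-network building blocks on top of :mod:`aamm.autodiff`.

Only what the package's two models need: linear layers, an MLP with a
choice of hidden activation, and an Adam optimizer.  Parameters are plain
:class:`~aamm.autodiff.Tensor` objects with ``requires_grad=True``;
modules expose ``parameters()`` returning them in a stable order so that
optimizer state and checkpoints are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, relu, tanh

_ACTIVATIONS = {"relu": relu, "tanh": tanh, "linear": lambda x: x}


class Linear:
    """Affine map ``x @ W + b`` with Glorot-style init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = Tensor(rng.normal(0.0, scale, (d_in, d_out)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        if isinstance(x, Tensor):
            return x @ self.W + self.b
        return x @ self.W.data + self.b.data

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Stack of linear layers; ``activation`` applied between them only."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 activation: str = "relu", dtype=np.float32):
        self.layers = [Linear(a, b, rng, dtype=dtype)
                       for a, b in zip(dims[:-1], dims[1:])]
        self.act = _ACTIVATIONS[activation]

    def __call__(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = self.act(x)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam optimizer with optional decoupled weight decay (AdamW-style)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self._buf = [np.empty_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            m, v, buf = self.m[i], self.v[i], self._buf[i]
            # in-place, buffer-reusing update: per-bag steps make this hot
            m *= self.b1
            np.multiply(g, 1 - self.b1, out=buf)
            m += buf
            v *= self.b2
            np.multiply(g, g, out=buf)
            buf *= 1 - self.b2
            v += buf
            np.divide(v, c2, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= self.lr / c1
            p.data -= buf
            if self.weight_decay:
                p.data -= (self.lr * self.weight_decay) * p.data
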