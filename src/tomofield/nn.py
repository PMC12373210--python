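"""Dense/convolutional building blocks and the RMSprop update rule.

Everything is seeded explicitly: layers are initialized from an injected
`numpy.random.Generator`, parameters are plain :class:`~tomofield._autodiff.Tensor`
objects, and state dicts are nested lists of arrays (JSON/NPZ friendly).
"""

from __future__ import annotations

import numpy as np

from ._autodiff import DTYPE, Tensor, affine, conv2d, conv3d, upsample_nearest


class Module:
    def parameters(self) -> list[Tensor]:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=DTYPE).copy()


class Linear(Module):
    """Affine layer y = x W + b with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return affine(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class Conv(Module):
    """k^d convolution (d = 2 or 3), optional stride, 'same'-style padding."""

    def __init__(self, ndim: int, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, pad: int | None = None):
        self.ndim = ndim
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = c_in * k**ndim
        shape = (c_out, c_in) + (k,) * ndim
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        op = conv2d if self.ndim == 2 else conv3d
        return op(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def parameters(self):
        return [self.w, self.b]


class MLP(Module):
    """Fully connected ReLU network; the final layer is linear."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


def upsample(x: Tensor, factor: int = 2) -> Tensor:
    return upsample_nearest(x, factor)


class RMSprop:
    """Root-mean-square propagation with decay `alpha` (adaptive step sizes)."""

    def __init__(self, params: list[Tensor], lr: float, alpha: float = 0.99, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.sq = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, sq in zip(self.params, self.sq):
            if p.grad is None:
                continue
            g = p.grad
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(sq) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
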