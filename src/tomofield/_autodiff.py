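"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor engine: just the operations the density-field
generator, the convolutional discriminators and the loss terms need
(dense/convolution layers, ReLU/softplus, reductions, logarithms).  Arrays are
float32 by default; gradients are accumulated by a topological backward sweep.
No global state — graphs are built per forward pass and freed afterwards.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- niceties ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
            node._backward = None
            node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        # out-of-place accumulation: gradients may be shared views, so never
        # mutate a stored array in place
        if self.grad is None:
            self.grad = g if g.dtype == DTYPE else g.astype(DTYPE)
        else:
            self.grad = self.grad + g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def softplus(self):
        # numerically stable log(1 + exp(x)); float32 is ample here
        y = np.logaddexp(DTYPE(0.0), self.data)
        out = Tensor(y, _parents=(self,))
        sig = DTYPE(1.0) / (DTYPE(1.0) + np.exp(-self.data))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * sig)

        out._backward = bwd
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(DTYPE))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).astype(DTYPE))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def rows(self, start: int, stop: int):
        """Contiguous row slice with gradient scatter-back."""
        out = Tensor(self.data[start:stop], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                gg = np.zeros_like(self.data)
                gg[start:stop] = g
                self._accum(gg)

        out._backward = bwd
        return out

    def flip(self, axis: int):
        out = Tensor(np.flip(self.data, axis=axis), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(np.flip(g, axis=axis))
        return out

    def transpose(self, axes: tuple[int, ...]):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.data.shape))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def affine(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused x @ w + b (b broadcasting over rows) in a single graph node."""
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    out = Tensor(x.data @ w.data + b.data, _parents=(x, w, b))

    def bwd(g):
        if x.requires_grad:
            x._accum(g @ w.data.T)
        if w.requires_grad:
            w._accum(x.data.T @ g)
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Convolutions (small kernels; shifted-slice accumulation, stride support)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (N,C,H,W), w: (O,C,kh,kw) -> (N,O,H',W')."""
    N, C, H, W = x.data.shape
    O, _, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    out_data = np.zeros((N, O, OH, OW), dtype=DTYPE)
    for a in range(kh):
        for c in range(kw):
            xs = xp[:, :, a : a + stride * OH : stride, c : c + stride * OW : stride]
            out_data += np.einsum("nchw,oc->nohw", xs, w.data[:, :, a, c], optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(xp)
            for a in range(kh):
                for c in range(kw):
                    gx[:, :, a : a + stride * OH : stride, c : c + stride * OW : stride] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, a, c], optimize=True
                    )
            x._accum(gx[:, :, pad : pad + H, pad : pad + W] if pad else gx)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for a in range(kh):
                for c in range(kw):
                    xs = xp[:, :, a : a + stride * OH : stride, c : c + stride * OW : stride]
                    gw[:, :, a, c] = np.einsum("nohw,nchw->oc", g, xs, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._backward = bwd
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (N,C,D,H,W), w: (O,C,kd,kh,kw) -> (N,O,D',H',W')."""
    N, C, D, H, W = x.data.shape
    O, _, kd, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    Dp, Hp, Wp = xp.shape[2:]
    OD = (Dp - kd) // stride + 1
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    out_data = np.zeros((N, O, OD, OH, OW), dtype=DTYPE)
    for a in range(kd):
        for bb in range(kh):
            for c in range(kw):
                xs = xp[
                    :,
                    :,
                    a : a + stride * OD : stride,
                    bb : bb + stride * OH : stride,
                    c : c + stride * OW : stride,
                ]
                out_data += np.einsum("ncdhw,oc->nodhw", xs, w.data[:, :, a, bb, c], optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, O, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(xp)
            for a in range(kd):
                for bb in range(kh):
                    for c in range(kw):
                        gx[
                            :,
                            :,
                            a : a + stride * OD : stride,
                            bb : bb + stride * OH : stride,
                            c : c + stride * OW : stride,
                        ] += np.einsum("nodhw,oc->ncdhw", g, w.data[:, :, a, bb, c], optimize=True)
            x._accum(gx[:, :, pad : pad + D, pad : pad + H, pad : pad + W] if pad else gx)
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for a in range(kd):
                for bb in range(kh):
                    for c in range(kw):
                        xs = xp[
                            :,
                            :,
                            a : a + stride * OD : stride,
                            bb : bb + stride * OH : stride,
                            c : c + stride * OW : stride,
                        ]
                        gw[:, :, a, bb, c] = np.einsum("nodhw,ncdhw->oc", g, xs, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    out._backward = bwd
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling of the trailing spatial axes of (N,C,...)."""
    nd = x.data.ndim - 2
    data = x.data
    for ax in range(2, 2 + nd):
        data = np.repeat(data, factor, axis=ax)
    out = Tensor(data, _parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        shape = []
        for i, s in enumerate(x.data.shape):
            if i < 2:
                shape.append(s)
            else:
                shape.extend([s, factor])
        g2 = g.reshape(shape)
        g2 = g2.sum(axis=tuple(range(3, 3 + 2 * nd, 2)))
        x._accum(g2)

    out._backward = bwd
    return out
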