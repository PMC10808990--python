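"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 numpy array and records the operations
applied to it on a tape; :meth:`Tensor.backward` runs the tape in
reverse topological order. The op set is exactly what a center-point
detector needs: elementwise arithmetic, log/abs/clip, relu/sigmoid,
reductions, 2-D convolution, batch normalization and 2× bilinear
upsampling. Gradient correctness of every op is checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce *grad* back to *shape* after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # defer mixed ndarray/Tensor arithmetic to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction -------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        if exponent == 1.0:
            return self
        if exponent == 2.0:
            return self._make(self.data * self.data, (self,), lambda g: (2.0 * g * self.data,))

        def backward(g):
            # subgradient 0 where the power's derivative is singular
            with np.errstate(divide="ignore", invalid="ignore"):
                d = exponent * self.data ** (exponent - 1.0)
            d = np.where(np.isfinite(d), d, 0.0)
            return (g * d,)

        return self._make(self.data**exponent, (self,), backward)

    # -- elementwise nonlinearities -----------------------------------

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def abs(self):
        return self._make(np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            return (g * mask,)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out * (1.0 - out),)

        return self._make(out, (self,), backward)

    # -- reductions ----------------------------------------------------

    def sum(self):
        def backward(g):
            return (np.full(self.shape, g, dtype=DTYPE),)

        return self._make(self.data.sum(), (self,), backward)

    def mean(self):
        n = self.data.size

        def backward(g):
            return (np.full(self.shape, g / n, dtype=DTYPE),)

        return self._make(self.data.mean(), (self,), backward)

    # -- backprop ------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.asarray(g, dtype=DTYPE)
                else:
                    parent.grad = parent.grad + g
            # free the tape as we go
            node._backward = None
            node._parents = ()


# -- structured ops ----------------------------------------------------


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, square kernel.

    Implemented as a shift-and-matmul over kernel taps so both passes
    run through BLAS.
    """
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    assert cin == cin_w, f"channel mismatch {cin} vs {cin_w}"
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    out_flat = np.zeros((cout, n * ho * wo), dtype=DTYPE)
    slices = []
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            x2 = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(cin, -1)
            slices.append(x2)
            out_flat += weight.data[:, :, i, j] @ x2
    out = out_flat.reshape(cout, n, ho, wo).transpose(1, 0, 2, 3)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g_flat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
        gw = np.zeros_like(weight.data)
        gxp = np.zeros_like(xp)
        for idx, (i, j) in enumerate((i, j) for i in range(kh) for j in range(kw)):
            gw[:, :, i, j] = g_flat @ slices[idx].T
            gx2 = weight.data[:, :, i, j].T @ g_flat
            gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                gx2.reshape(cin, n, ho, wo).transpose(1, 0, 2, 3)
            )
        gx = gxp[:, :, padding : padding + h, padding : padding + w] if padding else gxp
        if bias is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    t = Tensor(out)
    t.requires_grad = any(p.requires_grad for p in parents)
    if t.requires_grad:
        t._parents = parents
        t._backward = backward
    return t


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                running_var: np.ndarray, training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode batch statistics are used and the running buffers
    updated in place; in eval mode the running buffers are used.
    """
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) / std.reshape(1, -1, 1, 1)
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        ggamma = (g * xhat).sum(axis=axes)
        gbeta = g.sum(axis=axes)
        if training:
            m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            gs = gamma.data.reshape(1, -1, 1, 1) / std.reshape(1, -1, 1, 1)
            gx = gs * (
                g
                - gbeta.reshape(1, -1, 1, 1) / m
                - xhat * ggamma.reshape(1, -1, 1, 1) / m
            )
        else:
            gx = g * (gamma.data / std).reshape(1, -1, 1, 1)
        return gx, ggamma, gbeta

    t = Tensor(out)
    t.requires_grad = x.requires_grad or gamma.requires_grad or beta.requires_grad
    if t.requires_grad:
        t._parents = (x, gamma, beta)
        t._backward = backward
    return t


def _interp_indices(n_out: int, n_in: int):
    src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(np.intp), 0, n_in - 1)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = np.clip(src - np.floor(src), 0.0, 1.0).astype(DTYPE)
    w1[src < 0] = 0.0
    return i0, i1, (1.0 - w1), w1


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear 2× upsampling (half-pixel centers, edge replication)."""
    n, c, h, w = x.shape
    ri0, ri1, rw0, rw1 = _interp_indices(2 * h, h)
    ci0, ci1, cw0, cw1 = _interp_indices(2 * w, w)

    rows = x.data[:, :, ri0, :] * rw0[None, None, :, None] + \
        x.data[:, :, ri1, :] * rw1[None, None, :, None]
    out = rows[:, :, :, ci0] * cw0[None, None, None, :] + \
        rows[:, :, :, ci1] * cw1[None, None, None, :]

    def backward(g):
        grows = np.zeros((n, c, 2 * h, w), dtype=DTYPE)
        np.add.at(grows, (slice(None), slice(None), slice(None), ci0),
                  g * cw0[None, None, None, :])
        np.add.at(grows, (slice(None), slice(None), slice(None), ci1),
                  g * cw1[None, None, None, :])
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), ri0, slice(None)),
                  grows * rw0[None, None, :, None])
        np.add.at(gx, (slice(None), slice(None), ri1, slice(None)),
                  grows * rw1[None, None, :, None])
        return (gx,)

    t = Tensor(out)
    t.requires_grad = x.requires_grad
    if t.requires_grad:
        t._parents = (x,)
        t._backward = backward
    return t
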