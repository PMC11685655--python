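"""Minimal reverse-mode automatic differentiation on numpy arrays.

The translation networks in this package are small convolutional graphs that
must train on a plain CPU, so the engine implements exactly the operator set
those graphs need: broadcasted arithmetic, matmul, reductions, element-wise
nonlinearities, 2-D convolution (im2col), average pooling, reflection/zero
padding, bilinear 2x upsampling, concatenation and slicing.

A :class:`Tensor` wraps an ``ndarray`` and records its parents and a backward
closure; :meth:`Tensor.backward` runs the tape in reverse topological order.
Gradients accumulate into ``.grad`` for every tensor created with
``requires_grad=True`` (and, transitively, results that depend on one).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_tensors", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _as_array(data, dtype=None):
    a = np.asarray(data)
    if dtype is not None:
        return a.astype(dtype, copy=False)
    if a.dtype.kind != "f":
        return a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED[0] and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _parents=parents if req else ())
        if req:
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.data.shape))
        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))
        return self._make(self.data ** e, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def __matmul__(self, other):
        other = self._lift(other)
        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gk = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gk, self.data.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- element-wise nonlinearities ---------------------------------------
    def abs(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))
        return self._make(np.abs(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0
        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)
        return self._make(self.data * mask, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, negative_slope).astype(self.data.dtype)
        def backward(g):
            if self.requires_grad:
                self._accum(g * scale)
        return self._make(self.data * scale, (self,), backward)

    def tanh(self):
        out = np.tanh(self.data)
        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out ** 2))
        return self._make(out, (self,), backward)

    def sigmoid(self):
        # numerically stable logistic
        out = np.empty_like(self.data)
        pos = self.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out[~pos] = ex / (1.0 + ex)
        def backward(g):
            if self.requires_grad:
                self._accum(g * out * (1.0 - out))
        return self._make(out, (self,), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))
        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)
        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))
        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accum(full)
        return self._make(self.data[key], (self,), backward)

    # -- spatial ops (NCHW) --------------------------------------------------
    def pad2d(self, pad: int, mode: str = "reflect"):
        """Pad the two trailing axes by `pad` pixels ('reflect' or 'zero')."""
        if pad == 0:
            return self
        n, c, h, w = self.data.shape
        if mode == "zero":
            out = np.pad(self.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
            def backward(g):
                if self.requires_grad:
                    self._accum(g[:, :, pad:pad + h, pad:pad + w])
            return self._make(out, (self,), backward)
        idx_h = _reflect_index(h, pad)
        idx_w = _reflect_index(w, pad)
        out = self.data[:, :, idx_h][:, :, :, idx_w]
        def backward(g):
            if self.requires_grad:
                folded = _fold_axis(_fold_axis(g, idx_h, 2, h), idx_w, 3, w)
                self._accum(folded)
        return self._make(out, (self,), backward)

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, stride: int = 1):
        """2-D convolution, NCHW input, OIHW weight; no implicit padding."""
        x, w = self.data, weight.data
        n, cin, h, ww = x.shape
        cout, cin2, kh, kw = w.shape
        if cin != cin2:
            raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin2}")
        ho = (h - kh) // stride + 1
        wo = (ww - kw) // stride + 1
        view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        view = view[:, :, ::stride, ::stride]              # (N,C,Ho,Wo,kh,kw)
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)
        wmat = w.reshape(cout, cin * kh * kw)
        out = cols @ wmat.T
        if bias is not None:
            out = out + bias.data
        out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            gflat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
            if bias is not None and bias.requires_grad:
                bias._accum(gflat.sum(axis=0))
            if weight.requires_grad:
                weight._accum((gflat.T @ cols).reshape(w.shape))
            if self.requires_grad:
                dcols = (gflat @ wmat).reshape(n, ho, wo, cin, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                dx = np.zeros_like(x)
                for i in range(kh):
                    for j in range(kw):
                        dx[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += dcols[:, :, :, :, i, j]
                self._accum(dx)

        return self._make(out, parents, backward)

    def avg_pool2d(self, kernel: int = 2):
        """Non-overlapping average pooling (stride = kernel)."""
        n, c, h, w = self.data.shape
        if h % kernel or w % kernel:
            raise ValueError(f"avg_pool2d: spatial size {(h, w)} not divisible by {kernel}")
        r = self.data.reshape(n, c, h // kernel, kernel, w // kernel, kernel)
        out = r.mean(axis=(3, 5))
        inv = 1.0 / kernel ** 2
        def backward(g):
            if self.requires_grad:
                gup = np.repeat(np.repeat(g, kernel, axis=2), kernel, axis=3) * inv
                self._accum(gup)
        return self._make(out, (self,), backward)

    def instance_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Fused per-sample, per-channel spatial normalisation with affine."""
        x = self.data
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = gamma.data * xhat + beta.data

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3), keepdims=True))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3), keepdims=True))
            if self.requires_grad:
                dxhat = g * gamma.data
                m1 = dxhat.mean(axis=(2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
                self._accum(inv * (dxhat - m1 - xhat * m2))

        return self._make(out, (self, gamma, beta), backward)

    def upsample_bilinear2x(self):
        """Bilinear x2 upsampling (half-pixel centres, edges clamped)."""
        n, c, h, w = self.data.shape
        mh = _bilinear_matrix(h)
        mw = _bilinear_matrix(w)
        out = np.matmul(np.matmul(mh, self.data), mw.T)
        def backward(g):
            if self.requires_grad:
                self._accum(np.matmul(np.matmul(mh.T, g), mw))
        return self._make(out, (self,), backward)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and (p.requires_grad or p._parents):
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = _GRAD_ENABLED[0] and any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _parents=tuple(tensors) if req else ())
    if req:
        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])
        out._backward = backward
    return out


def stack_tensors(tensors) -> Tensor:
    """Stack scalars/arrays along a new leading axis."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=0)
    req = _GRAD_ENABLED[0] and any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _parents=tuple(tensors) if req else ())
    if req:
        def backward(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(g[i])
        out._backward = backward
    return out


# -- cached helpers ----------------------------------------------------------

_BILINEAR_CACHE: dict[int, np.ndarray] = {}


def _bilinear_matrix(n: int) -> np.ndarray:
    m = _BILINEAR_CACHE.get(n)
    if m is None:
        m = np.zeros((2 * n, n), dtype=np.float32)
        for o in range(2 * n):
            centre = (o + 0.5) / 2.0 - 0.5
            f = int(np.floor(centre))
            t = centre - f
            f0 = min(max(f, 0), n - 1)
            f1 = min(max(f + 1, 0), n - 1)
            m[o, f0] += 1.0 - t
            m[o, f1] += t
        _BILINEAR_CACHE[n] = m
    return m


def _reflect_index(n: int, pad: int) -> np.ndarray:
    if pad >= n:
        raise ValueError(f"reflection pad {pad} needs input size > pad (got {n})")
    idx = np.abs(np.arange(-pad, n + pad))
    return np.where(idx >= n, 2 * (n - 1) - idx, idx)


def _fold_axis(grad: np.ndarray, idx: np.ndarray, axis: int, n: int) -> np.ndarray:
    g = np.moveaxis(grad, axis, 0)
    out = np.zeros((n,) + g.shape[1:], dtype=g.dtype)
    np.add.at(out, idx, g)
    return np.moveaxis(out, 0, axis)
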