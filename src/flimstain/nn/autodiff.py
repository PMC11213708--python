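"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the staining networks and the DISTS loss
need: broadcast arithmetic, reductions, 2-D convolution (im2col), pooling,
nearest-neighbour upsampling, concatenation and pointwise nonlinearities.
Gradients accumulate into ``Tensor.grad`` on ``backward()``; the tape is a
topologically ordered list of nodes built eagerly during the forward pass.

All computation is plain numpy, so results are bit-reproducible on a fixed
platform and dtype follows the inputs (float32 for training, float64 where
tests need tight tolerances).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
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
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs are deep during training
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / out.data)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), parents=(self,))
        out._backward = lambda g: self._accum(g * np.where(self.data > 0, 1.0, slope))
        return out

    # ---------------------------------------------------------- image-shaped
    def pad2d(self, pad: int, mode: str = "constant", value: float = 0.0):
        """Pad the last two axes of an (N, C, H, W) tensor."""
        if pad == 0:
            return self
        spec = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        if mode == "constant":
            data = np.pad(self.data, spec, mode="constant", constant_values=value)
        else:
            data = np.pad(self.data, spec, mode=mode)
        out = Tensor(data, parents=(self,))
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
        if mode == "constant":
            out._backward = lambda g: self._accum(g[sl])
        else:  # reflect: scatter-add via explicit inverse is overkill; forbid grads
            def bwd(_g):
                raise NotImplementedError("grad through non-constant pad")

            out._backward = bwd
        return out

    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation, x:(N,C,H,W) * w:(F,C,kh,kw) -> (N,F,Ho,Wo)."""
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        f, _, kh, kw = w.shape
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (xp.shape[2] - kh) // s + 1
        wo = (xp.shape[3] - kw) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # (N,C,Ho,Wo,kh,kw)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
        wmat = w.reshape(f, -1)
        y = cols @ wmat.T
        if bias is not None:
            y = y + bias.data
        y = y.reshape(n, ho, wo, f).transpose(0, 3, 1, 2)
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor(np.ascontiguousarray(y), parents=parents)

        def bwd(g):
            g2 = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, f)
            if bias is not None and bias.requires_grad:
                bias._accum(g2.sum(axis=0))
            if weight.requires_grad:
                weight._accum((g2.T @ cols).reshape(w.shape))
            if self.requires_grad:
                dcols = (g2 @ wmat).reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                dxp = np.zeros_like(xp)
                for i in range(kh):          # kernel loop: 9–16 vectorised adds
                    for j in range(kw):
                        dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j]
                self._accum(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

        out._backward = bwd
        return out

    def avg_pool2d(self, k: int = 2):
        n, c, h, w = self.shape
        ho, wo = h // k, w // k
        out = Tensor(
            self.data[:, :, :ho * k, :wo * k]
            .reshape(n, c, ho, k, wo, k).mean(axis=(3, 5)),
            parents=(self,),
        )

        def bwd(g):
            dx = np.zeros_like(self.data)
            dx[:, :, :ho * k, :wo * k] = np.repeat(
                np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            self._accum(dx)

        out._backward = bwd
        return out

    def depth_to_space(self, k: int = 2):
        """(N, C*k*k, H, W) -> (N, C, H*k, W*k) pixel shuffle."""
        n, ck, h, w = self.shape
        c = ck // (k * k)
        out_data = (self.data.reshape(n, c, k, k, h, w)
                    .transpose(0, 1, 4, 2, 5, 3).reshape(n, c, h * k, w * k))
        out = Tensor(np.ascontiguousarray(out_data), parents=(self,))

        def bwd(g):
            self._accum(g.reshape(n, c, h, k, w, k)
                        .transpose(0, 1, 3, 5, 2, 4).reshape(n, ck, h, w))

        out._backward = bwd
        return out

    def upsample_nearest(self, k: int = 2):
        out = Tensor(np.repeat(np.repeat(self.data, k, axis=2), k, axis=3),
                     parents=(self,))

        def bwd(g):
            n, c, h, w = self.shape
            self._accum(g.reshape(n, c, h, k, w, k).sum(axis=(3, 5)))

        out._backward = bwd
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to each input."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bwd
    return out
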