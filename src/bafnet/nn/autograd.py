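"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the primitives the segmentation network needs:
broadcast arithmetic, batched matmul, shape ops, windowed gathers, 2-D
convolution / transposed convolution / pooling, and the usual pointwise
nonlinearities.  Gradients are accumulated by a topological sweep over the
recorded tape.  Everything is single-threaded NumPy, so results are bit
reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf, expit

__all__ = ["Tensor", "concat", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape recording (inference mode).

    Inside the context no backward closures are created, so large forward
    intermediates (im2col buffers, attention matrices) are freed eagerly.
    """

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=np.float64 if np.ndim(x) == 0 else None))


class Tensor:
    """An ndarray plus the tape entry that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp = None

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._vjp = vjp
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._vjp is not None:
                for p, pg in zip(t._parents, t._vjp(g)):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            else:
                if t.grad is None:
                    t.grad = g.astype(t.data.dtype, copy=False)
                else:
                    t.grad = t.grad + g

    # -------------------------------------------------------------- arithmetic
    # Python scalars take a fast path that keeps the array dtype (float32
    # models stay float32) and records a single-parent tape entry.
    def __add__(self, other):
        if isinstance(other, (int, float)):
            a = self
            return Tensor._make(a.data + other, (a,), lambda g: (g,))
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            a = self
            return Tensor._make(a.data - other, (a,), lambda g: (g,))
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data - b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
        )

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            a = self
            return Tensor._make(other - a.data, (a,), lambda g: (-g,))
        return _as_tensor(other).__sub__(self)

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            a = self
            return Tensor._make(a.data * other, (a,), lambda g: (g * other,))
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self.__mul__(1.0 / other)
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.shape),
            ),
        )

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            a = self
            return Tensor._make(
                other / a.data, (a,), lambda g: (-g * other / (a.data * a.data),)
            )
        return _as_tensor(other).__truediv__(self)

    def __pow__(self, p: float):
        a = self
        return Tensor._make(
            a.data ** p, (a,), lambda g: (g * p * a.data ** (p - 1),)
        )

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        out = a.data @ b.data

        def vjp(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._make(out, (a, b), vjp)

    # --------------------------------------------------------------- pointwise
    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: (g * out,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor._make(out, (a,), lambda g: (g / (2.0 * out),))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        out = expit(a.data)
        return Tensor._make(out, (a,), lambda g: (g * out * (1.0 - out),))

    def gelu(self):
        """Exact (erf-based) GELU."""
        a = self
        x = a.data
        # Python-float constants keep float32 activations float32 (NEP 50)
        cdf = 0.5 * (1.0 + erf(x * float(1.0 / np.sqrt(2.0))))
        pdf = np.exp(-0.5 * x * x) * float(1.0 / np.sqrt(2.0 * np.pi))
        return Tensor._make(x * cdf, (a,), lambda g: (g * (cdf + x * pdf),))

    def clip(self, lo: float, hi: float):
        a = self
        mask = (a.data >= lo) & (a.data <= hi)
        return Tensor._make(np.clip(a.data, lo, hi), (a,), lambda g: (g * mask,))

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """A constant (non-differentiated) max, used to stabilise softmax."""
        return self.data.max(axis=axis, keepdims=keepdims)

    def softmax(self, axis: int = -1):
        z = self - self.max_detached(axis=axis, keepdims=True)
        e = z.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # ---------------------------------------------------------------- reshapes
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        a = self

        def vjp(g):
            out = np.zeros_like(a.data)
            out[idx] = g
            return (out,)

        return Tensor._make(a.data[idx], (a,), vjp)

    def roll(self, shifts, axes):
        a = self
        neg = tuple(-s for s in shifts)
        return Tensor._make(
            np.roll(a.data, shifts, axis=axes),
            (a,),
            lambda g: (np.roll(g, neg, axis=axes),),
        )

    def pad2d(self, pads, mode: str = "constant"):
        """Pad the last two axes; ``pads`` = (top, bottom, left, right)."""
        a = self
        t, b, l, r = pads
        if t == b == l == r == 0:
            return a
        width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
        H, W = a.shape[-2], a.shape[-1]
        if mode == "constant":
            def vjp(g):
                sl = [slice(None)] * (a.ndim - 2) + [slice(t, t + H), slice(l, l + W)]
                return (g[tuple(sl)],)

            return Tensor._make(np.pad(a.data, width), (a,), vjp)
        if mode == "reflect":
            # index maps so the backward pass can scatter-accumulate
            ri = np.pad(np.arange(H), (t, b), mode="reflect")
            ci = np.pad(np.arange(W), (l, r), mode="reflect")

            def vjp(g):
                gr = np.zeros(a.shape[:-2] + (H, a.shape[-1] + l + r), dtype=g.dtype)
                np.add.at(gr, (..., ri, slice(None)), g)
                out = np.zeros(a.shape, dtype=g.dtype)
                np.add.at(out, (..., slice(None), ci), gr)
                return (out,)

            return Tensor._make(np.pad(a.data, width, mode="reflect"), (a,), vjp)
        raise ValueError(f"unknown pad mode {mode!r}")

    # --------------------------------------------------------- gathers / misc
    def gather_rows(self, index: np.ndarray):
        """``out[..., :] = self[index]`` for an integer index array (first axis)."""
        a = self
        idx = np.asarray(index)

        def vjp(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a.data[idx], (a,), vjp)

    # --------------------------------------------------------------- conv ops
    def conv2d(self, weight: "Tensor", bias=None, padding: int = 0):
        """Stride-1 2-D convolution; self (B,C,H,W), weight (O,C,k,k)."""
        a, w = self, weight
        B, C, H, W = a.shape
        O, Cw, kh, kw = w.shape
        if C != Cw:
            raise ValueError(f"conv2d: input has {C} channels, weight expects {Cw}")
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
        Ho, Wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        view = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,Ho,Wo,kh,kw
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho * Wo, C * kh * kw)
        wmat = w.data.reshape(O, C * kh * kw)
        out = cols @ wmat.T  # B, Ho*Wo, O
        out = out.transpose(0, 2, 1).reshape(B, O, Ho, Wo)

        def vjp(g):
            g2 = g.reshape(B, O, Ho * Wo).transpose(0, 2, 1)  # B,N,O
            gw = np.einsum("bno,bnk->ok", g2, cols).reshape(w.shape)
            gcols = (g2 @ wmat).reshape(B, Ho, Wo, C, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + Ho, j : j + Wo] += gcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            if padding:
                gxp = gxp[:, :, padding : padding + H, padding : padding + W]
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gxp, gw) if bias is None else (gxp, gw, gb)

        parents = (a, w) if bias is None else (a, w, bias)
        res = Tensor._make(out, parents, vjp)
        if bias is not None:
            # fold bias into the forward value (vjp above already covers it)
            res.data = res.data + bias.data.reshape(1, O, 1, 1)
        return res

    def conv_transpose2d_2x(self, weight: "Tensor", bias=None):
        """Stride-2, kernel-2 transposed convolution (exact 2x upsampling).

        self (B,C,H,W), weight (C,O,2,2) -> (B,O,2H,2W).
        """
        a, w = self, weight
        B, C, H, W = a.shape
        Cw, O = w.shape[0], w.shape[1]
        if C != Cw:
            raise ValueError("conv_transpose2d: channel mismatch")
        out = np.einsum("bchw,coij->bohiwj", a.data, w.data).reshape(B, O, 2 * H, 2 * W)

        def vjp(g):
            g6 = g.reshape(B, O, H, 2, W, 2)
            gx = np.einsum("bohiwj,coij->bchw", g6, w.data)
            gw = np.einsum("bchw,bohiwj->coij", a.data, g6)
            gb = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (gx, gw) if bias is None else (gx, gw, gb)

        parents = (a, w) if bias is None else (a, w, bias)
        res = Tensor._make(out, parents, vjp)
        if bias is not None:
            res.data = res.data + bias.data.reshape(1, O, 1, 1)
        return res

    def avg_pool2d(self, k: int):
        """Non-overlapping average pooling with kernel = stride = k."""
        if k == 1:
            return self
        a = self
        B, C, H, W = a.shape
        if H % k or W % k:
            raise ValueError(f"avg_pool2d: {H}x{W} not divisible by {k}")
        out = a.data.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))

        def vjp(g):
            g = g[:, :, :, None, :, None] / (k * k)
            return (np.broadcast_to(g, (B, C, H // k, k, W // k, k)).reshape(a.shape).copy(),)

        return Tensor._make(out, (a,), vjp)

    def upsample_nearest(self, k: int):
        """Nearest-neighbour upsampling by an integer factor."""
        if k == 1:
            return self
        a = self
        B, C, H, W = a.shape
        out = np.broadcast_to(
            a.data[:, :, :, None, :, None], (B, C, H, k, W, k)
        ).reshape(B, C, H * k, W * k)

        def vjp(g):
            return (g.reshape(B, C, H, k, W, k).sum(axis=(3, 5)),)

        return Tensor._make(out.copy(), (a,), vjp)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tensors, vjp)
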