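"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the
multi-domain layers need: broadcasted arithmetic, reductions, shape
ops, 2-D grouped convolution and pooling, elementwise transcendentals
(including ``atan2`` and ``erf``), and the real 2-D Fourier transform
pair used by the frequency-domain modules.  Gradients of every
primitive are verified against central finite differences in the test
suite.

All data is kept in ``float64``; the networks built on top are small
enough that precision is worth more than speed here.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "conv2d",
    "maxpool2d",
    "avgpool2d",
    "fft2_re",
    "fft2_im",
    "ifft2_real",
    "hypot",
    "atan2",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.data.shape))

        out._backward = bwd
        return out

    # -- elementwise transcendentals -----------------------------------
    def _unary(self, fval: np.ndarray, dfn) -> "Tensor":
        out = Tensor(fval, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * dfn())

        out._backward = bwd
        return out

    def exp(self):
        v = np.exp(self.data)
        return self._unary(v, lambda: v)

    def log(self):
        return self._unary(np.log(self.data), lambda: 1.0 / self.data)

    def sqrt(self):
        v = np.sqrt(self.data)
        return self._unary(v, lambda: 0.5 / v)

    def sin(self):
        return self._unary(np.sin(self.data), lambda: np.cos(self.data))

    def cos(self):
        return self._unary(np.cos(self.data), lambda: -np.sin(self.data))

    def erf(self):
        return self._unary(
            _erf(self.data),
            lambda: 2.0 / np.sqrt(np.pi) * np.exp(-self.data ** 2))

    def sigmoid(self):
        v = np.where(self.data >= 0,
                     1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500))),
                     np.exp(np.clip(self.data, -500, 500))
                     / (1.0 + np.exp(np.clip(self.data, -500, 500))))
        return self._unary(v, lambda: v * (1.0 - v))

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)
        return self._unary(np.clip(self.data, lo, hi), lambda: mask.astype(np.float64))

    def relu(self):
        mask = self.data > 0
        return self._unary(np.where(mask, self.data, 0.0),
                           lambda: mask.astype(np.float64))

    # -- reductions & shape --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(src))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        out._backward = bwd
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    out._backward = bwd
    return out


# ----------------------------------------------------------------------
# convolution & pooling primitives
# ----------------------------------------------------------------------

def _windows(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(B, C, Ho, Wo, kh, kw) view of padded input."""
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int | tuple[int, int] = 0,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout, grouped.

    ``w`` has shape (Cout, Cin/groups, kh, kw); padding is symmetric
    zero padding (``int`` or ``(ph, pw)``).
    """
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    sh = sw = stride
    B, C, H, W = x.data.shape
    Cout, Cin_g, kh, kw = w.data.shape
    if C != Cin_g * groups:
        raise ValueError(
            f"channel mismatch: input has {C} channels, weights expect "
            f"{Cin_g * groups} ({groups} group(s) of {Cin_g})")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    v = _windows(xp, kh, kw, sh, sw)            # (B, C, Ho, Wo, kh, kw)
    Ho, Wo = v.shape[2], v.shape[3]
    og = Cout // groups
    # fold the group axis into one batched contraction
    vg = v.reshape(B, groups, Cin_g, Ho, Wo, kh, kw)
    wg = w.data.reshape(groups, og, Cin_g, kh, kw)
    out = np.einsum("bgchwij,gocij->bgohw", vg, wg,
                    optimize=True).reshape(B, Cout, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    res = Tensor(out, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        gg = g.reshape(B, groups, og, Ho, Wo)
        if w.requires_grad:
            w._accum(np.einsum("bgohw,bgchwij->gocij", gg, vg,
                               optimize=True).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(xp)
            gxg = gx.reshape(B, groups, Cin_g, *xp.shape[-2:])
            for i in range(kh):
                for j in range(kw):
                    gxg[:, :, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += np.einsum(
                        "bgohw,goc->bgchw", gg, wg[:, :, :, i, j],
                        optimize=True)
            if ph or pw:
                gx = gx[:, :, ph:ph + H, pw:pw + W]
            x._accum(gx)

    res._backward = bwd
    return res


def maxpool2d(x: Tensor, kernel: int, stride: int | None = None,
              padding: int = 0) -> Tensor:
    stride = stride or kernel
    B, C, H, W = x.data.shape
    pad_val = -np.inf if padding else 0.0
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=pad_val)
    v = _windows(xp, kernel, kernel, stride, stride)
    Ho, Wo = v.shape[2], v.shape[3]
    flat = v.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                 x.requires_grad, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xp)
        ii, jj = np.unravel_index(arg, (kernel, kernel))
        bi, ci, hi, wi = np.indices(arg.shape)
        np.add.at(gx, (bi, ci, hi * stride + ii, wi * stride + jj), g)
        if padding:
            gx = gx[:, :, padding:padding + H, padding:padding + W]
        x._accum(gx)

    out._backward = bwd
    return out


def avgpool2d(x: Tensor, kernel: int, stride: int | None = None,
              padding: int = 0) -> Tensor:
    stride = stride or kernel
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    v = _windows(xp, kernel, kernel, stride, stride)
    out = Tensor(v.mean(axis=(-2, -1)), x.requires_grad, (x,))
    Ho, Wo = out.data.shape[2], out.data.shape[3]

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(xp)
        share = g / (kernel * kernel)
        for i in range(kernel):
            for j in range(kernel):
                gx[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += share
        if padding:
            gx = gx[:, :, padding:padding + H, padding:padding + W]
        x._accum(gx)

    out._backward = bwd
    return out


# ----------------------------------------------------------------------
# Fourier primitives (last two axes)
# ----------------------------------------------------------------------

def fft2_re(x: Tensor) -> Tensor:
    """Real part of the unnormalized forward 2-D DFT of a real tensor."""
    out = Tensor(np.fft.fft2(x.data).real, x.requires_grad, (x,))
    # adjoint of the cos-matrix is itself: grad = Re(F g)
    out._backward = lambda g: x.requires_grad and x._accum(np.fft.fft2(g).real)
    return out


def fft2_im(x: Tensor) -> Tensor:
    """Imaginary part of the unnormalized forward 2-D DFT of a real tensor."""
    out = Tensor(np.fft.fft2(x.data).imag, x.requires_grad, (x,))
    out._backward = lambda g: x.requires_grad and x._accum(np.fft.fft2(g).imag)
    return out


def ifft2_real(re: Tensor, im: Tensor) -> Tensor:
    """Real part of the 1/(NM)-normalized inverse 2-D DFT of re + j·im."""
    out = Tensor(np.fft.ifft2(re.data + 1j * im.data).real,
                 re.requires_grad or im.requires_grad, (re, im))
    nm = re.data.shape[-1] * re.data.shape[-2]

    def bwd(g):
        G = np.fft.fft2(g) / nm
        if re.requires_grad:
            re._accum(G.real)
        if im.requires_grad:
            im._accum(G.imag)

    out._backward = bwd
    return out


def hypot(a: Tensor, b: Tensor) -> Tensor:
    """sqrt(a² + b²) with a zero (sub)gradient at the origin."""
    r = np.hypot(a.data, b.data)
    out = Tensor(r, a.requires_grad or b.requires_grad, (a, b))
    safe = np.where(r == 0.0, 1.0, r)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * a.data / safe)
        if b.requires_grad:
            b._accum(g * b.data / safe)

    out._backward = bwd
    return out


def atan2(y: Tensor, x: Tensor) -> Tensor:
    """Quadrant-aware angle of (x, y); zero gradient at the origin."""
    out = Tensor(np.arctan2(y.data, x.data),
                 y.requires_grad or x.requires_grad, (y, x))
    r2 = x.data ** 2 + y.data ** 2
    safe = np.where(r2 == 0.0, 1.0, r2)

    def bwd(g):
        if y.requires_grad:
            y._accum(g * x.data / safe)
        if x.requires_grad:
            x._accum(-g * y.data / safe)

    out._backward = bwd
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    val = z - lse
    out = Tensor(val, x.requires_grad, (x,))
    sm = np.exp(val)

    def bwd(g):
        if x.requires_grad:
            x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    out._backward = bwd
    return out
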