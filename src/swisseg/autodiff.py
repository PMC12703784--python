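"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the primitives the segmentation framework needs:
broadcasting arithmetic, matrix products, strided 2-D convolution, reductions,
activations, a fused softmax cross-entropy, nearest-neighbour upsampling and a
gradient reversal op. Tensors record their parents and a backward closure;
``Tensor.backward`` runs a topological sweep accumulating ``.grad`` arrays.

All computation is float32 by default and fully deterministic: no op uses
global random state, and the backward pass order is fixed by graph topology.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "grl", "cross_entropy", "SGD", "Adam"]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(_DTYPE, copy=False)
    return np.asarray(x, dtype=_DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array with an optional gradient and autodiff history."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data - other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            return g @ other.data.T, self.data.T @ g

        return Tensor._make(out_data, (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.1):
        factor = np.where(self.data > 0, 1.0, slope).astype(_DTYPE)
        return Tensor._make(self.data * factor, (self,), lambda g: (g * factor,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def softplus(self):
        # log(1 + e^x), computed stably; derivative is the logistic sigmoid
        out_data = np.logaddexp(0.0, self.data).astype(_DTYPE)

        def backward(g):
            sig = 1.0 / (1.0 + np.exp(-self.data))
            return (g * sig,)

        return Tensor._make(out_data, (self,), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.shape
        return Tensor._make(out_data, (self,), lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)
        return Tensor._make(out_data, (self,), lambda g: (g.transpose(inv),))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).astype(_DTYPE, copy=False),)
            g_exp = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g_exp, shape).astype(_DTYPE, copy=False),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- spatial ops ---------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               padding: int = 0) -> "Tensor":
        """2-D convolution (cross-correlation), NCHW layout."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        F, Cw, kh, kw = w.shape
        if Cw != C:
            raise ValueError(f"conv2d channel mismatch: input C={C}, weight C={Cw}")
        s, p = stride, padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        Hp, Wp = xp.shape[2:]
        OH, OW = (Hp - kh) // s + 1, (Wp - kw) // s + 1
        st = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, (B, C, kh, kw, OH, OW),
            (st[0], st[1], st[2], st[3], st[2] * s, st[3] * s))
        cols = np.ascontiguousarray(win.transpose(0, 4, 5, 1, 2, 3)).reshape(
            B * OH * OW, C * kh * kw)
        wmat = w.reshape(F, -1)
        out2d = cols @ wmat.T
        if bias is not None:
            out2d = out2d + bias.data
        out_data = out2d.reshape(B, OH, OW, F).transpose(0, 3, 1, 2)

        def backward(g):
            g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * OH * OW, F)
            dw = (g2d.T @ cols).reshape(w.shape)
            dcols = g2d @ wmat
            d6 = dcols.reshape(B, OH, OW, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += d6[:, :, i, j]
            dx = dxp[:, :, p:p + H, p:p + W] if p else dxp
            if bias is not None:
                return dx, dw, g2d.sum(axis=0)
            return dx, dw

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out_data, parents, backward)

    def upsample_nearest(self, factor: int) -> "Tensor":
        k = int(factor)
        out_data = self.data.repeat(k, axis=2).repeat(k, axis=3)
        B, C, H, W = self.shape

        def backward(g):
            return (g.reshape(B, C, H, k, W, k).sum(axis=(3, 5)),)

        return Tensor._make(out_data, (self,), backward)

    # -- backward pass -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, visited = [], set()

        def build(t):
            if id(t) in visited:
                return
            visited.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        grads = {id(self): _as_array(grad)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                pg = _as_array(pg)
                grads[key] = pg if key not in grads else grads[key] + pg


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def grl(x: Tensor, lambda_grl: float) -> Tensor:
    """Gradient reversal: identity forward, gradient scaled by -lambda backward."""
    if lambda_grl < 0:
        raise ValueError(f"lambda_grl must be nonnegative, got {lambda_grl}")
    x = x if isinstance(x, Tensor) else Tensor(x)
    lam = float(lambda_grl)
    return Tensor._make(x.data, (x,), lambda g: (-lam * g,))


def cross_entropy(logits: Tensor, target: np.ndarray, ignore_index: int = 255) -> Tensor:
    """Pixel-wise softmax cross-entropy averaged over non-ignored pixels.

    ``logits``: (B, K, H, W); ``target``: integer (B, H, W).
    """
    z = logits.data
    B, K, H, W = z.shape
    target = np.asarray(target)
    if target.shape != (B, H, W):
        raise ValueError(f"target shape {target.shape} != {(B, H, W)}")
    valid = target != ignore_index
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("cross_entropy: every pixel is ignore-labeled")
    zm = z - z.max(axis=1, keepdims=True)
    ez = np.exp(zm)
    softmax = ez / ez.sum(axis=1, keepdims=True)
    t_safe = np.where(valid, target, 0)
    idx_b, idx_h, idx_w = np.meshgrid(
        np.arange(B), np.arange(H), np.arange(W), indexing="ij")
    logp = zm - np.log(ez.sum(axis=1, keepdims=True))
    picked = logp[idx_b, t_safe, idx_h, idx_w]
    loss = -(picked * valid).sum() / n_valid

    def backward(g):
        grad = softmax.copy()
        grad[idx_b, t_safe, idx_h, idx_w] -= 1.0
        grad *= (valid / n_valid)[:, None, :, :]
        return (g * grad,)

    return Tensor._make(np.asarray(loss, dtype=_DTYPE), (logits,), backward)


# -- optimizers ---------------------------------------------------------------

class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
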