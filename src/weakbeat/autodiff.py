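"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine implements exactly the operations the detector's network needs:
broadcasting arithmetic, matmul, 1-D convolution (as shifted BLAS
matmuls), batch normalization, ReLU, dropout, max pooling,
nearest-neighbour upsampling, softmax, clipped logs and axis reductions.
Gradients are accumulated by a topologically ordered backward sweep over
the tape; interior nodes release their buffers as the sweep passes to cap
peak memory.

Arrays follow a channels-last layout throughout: a batch of signals is
``(batch, length, channels)``.
"""

from __future__ import annotations

import numpy as np

#: engine-wide float dtype.  float32 is the training default (the network is
#: memory-bound); switch to float64 for finite-difference gradient checking.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype)


__all__ = [
    "Tensor",
    "Parameter",
    "constant",
    "concat",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node of the computation tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    # -- arithmetic -----------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, (self, other))

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, (self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, (self, other))

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, (self, other))

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities -------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp; gradient passes only inside the open interval."""
        clipped = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(clipped, (self,))
        out._backward = lambda g: (g * mask,)
        return out

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int, keepdims=False):
        """Max along one axis; the subgradient routes to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis)
        out = Tensor(out_data, (self,))

        def backward(g):
            gx = np.zeros_like(self.data)
            g2 = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g2, axis)
            return (gx,)

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, (self,))

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        out._backward = backward
        return out

    # -- backward driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=DTYPE)
        leaves = {id(n) for n in topo if not n._parents}
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if parent.requires_grad and g is not None:
                    if parent.grad is None:
                        # copy: backward closures may hand back shared views
                        parent.grad = np.array(g, dtype=DTYPE)
                    else:
                        parent.grad += g
            # interior nodes are done: release their gradient and the
            # closure (which pins forward intermediates) to cap peak memory
            if id(node) not in leaves:
                node.grad = None
                node._backward = None


def release_memory() -> None:
    """Return freed allocator arenas to the OS (no-op off glibc).

    Long training sessions cycle through many megabyte-scale arrays;
    glibc retains freed arenas by default, which inflates resident
    memory across repeated runs in one process.
    """
    import ctypes

    try:
        ctypes.CDLL("libc.so.6").malloc_trim(0)
    except OSError:  # non-glibc platform
        pass


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# structured ops used by the 1-D network
# ---------------------------------------------------------------------------


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded 1-D convolution.

    x: (B, L, C_in); weight: (K, C_in, C_out); bias: (C_out,).
    Output: (B, L, C_out).  Evaluated as K shifted matmuls, which keeps
    every BLAS operand a contiguous 2-D slice (no im2col copy).
    """
    B, L, C = x.shape
    K, _, O = weight.shape
    pl, pr = (K - 1) // 2, K // 2
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    w = weight.data
    y = np.broadcast_to(bias.data, (B, L, O)).copy()
    for k in range(K):
        y += xp[:, k : k + L, :] @ w[k]
    out = Tensor(y, (x, weight, bias))

    def backward(g):
        gw = np.empty_like(w)
        dxp = np.zeros_like(xp)
        for k in range(K):
            xs = xp[:, k : k + L, :]
            gw[k] = np.matmul(xs.transpose(0, 2, 1), g).sum(axis=0)
            dxp[:, k : k + L, :] += g @ w[k].T
        gb = g.sum(axis=(0, 1))
        return (dxp[:, pl : pl + L, :], gw, gb)

    out._backward = backward
    return out


def maxpool1d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping max pooling along the time axis (floor length)."""
    B, L, C = x.shape
    L2 = L // pool
    xv = x.data[:, : L2 * pool, :].reshape(B, L2, pool, C)
    idx = np.argmax(xv, axis=2)
    out_data = np.take_along_axis(xv, idx[:, :, None, :], axis=2)[:, :, 0, :]
    out = Tensor(out_data, (x,))

    def backward(g):
        gx = np.zeros((B, L2, pool, C))
        np.put_along_axis(gx, idx[:, :, None, :], g[:, :, None, :], axis=2)
        gfull = np.zeros_like(x.data)
        gfull[:, : L2 * pool, :] = gx.reshape(B, L2 * pool, C)
        return (gfull,)

    out._backward = backward
    return out


def upsample_repeat(x: Tensor, factor: int, n: int) -> Tensor:
    """Nearest-neighbour upsampling by `factor`, right-extended to length n."""
    B, L, C = x.shape
    idx = np.minimum(np.arange(n) // factor, L - 1)
    out = Tensor(x.data[:, idx, :], (x,))

    def backward(g):
        gx = np.zeros_like(x.data)
        core = min(L * factor, n)
        nfull = core // factor
        gx[:, :nfull, :] = g[:, : nfull * factor, :].reshape(B, nfull, factor, C).sum(axis=2)
        if core > nfull * factor:
            gx[:, nfull, :] += g[:, nfull * factor : core, :].sum(axis=1)
        if n > L * factor:
            gx[:, -1, :] += g[:, L * factor :, :].sum(axis=1)
        return (gx,)

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if p <= 0:
        return x
    mask = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(DTYPE)
    return x * Tensor(mask)


class BatchNorm:
    """Per-channel batch normalization over (batch, time) for (B, L, C) input."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.data.mean(axis=(0, 1))
            var = x.data.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        out = Tensor(xhat * self.gamma.data + self.beta.data, (x, self.gamma, self.beta))
        N = x.data.shape[0] * x.data.shape[1]
        gamma = self.gamma.data

        def backward(g):
            dgamma = (g * xhat).sum(axis=(0, 1))
            dbeta = g.sum(axis=(0, 1))
            if train:
                gs = g.sum(axis=(0, 1))
                gxs = (g * xhat).sum(axis=(0, 1))
                dx = (gamma * inv / N) * (N * g - gs - xhat * gxs)
            else:
                dx = g * gamma * inv
            return (dx, dgamma, dbeta)

        out._backward = backward
        return out


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
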