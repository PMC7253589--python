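"""Minimal reverse-mode autodiff engine for 3D fully convolutional networks.

The whole architecture is built from a handful of coarse operations —
dilated 3D convolution, batch normalization, ReLU/sigmoid, broadcast
add/multiply, global average pooling and softmax cross-entropy — so a
small tape suffices.  Convolutions are lowered to BLAS matrix products
(see the note above ``_conv3d_raw``); the data gradient of a stride-1
"same" convolution is itself a "same" convolution with the spatially
flipped, channel-transposed kernel, which keeps the backward pass on
the same fast path.

Arrays keep the dtype they are given: networks run in float32, while
the numerical gradient checks in the test suite use float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "batch_norm",
    "relu",
    "sigmoid",
    "add",
    "mul",
    "reduce_sum",
    "global_avg_pool",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
    "no_grad",
]


class Tensor:
    """A numpy array plus the closures needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad=False, parents=()):
        self.data = np.asarray(data)
        self.grad = None
        if parents and not GRAD_ENABLED:
            parents = ()
            requires_grad = False
        self.requires_grad = requires_grad or any(p.requires_grad for p, _ in parents)
        self._parents = parents if self.requires_grad else ()

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.grad is None:
                continue
            for p, fn in t._parents:
                if not p.requires_grad:
                    continue
                g = fn(t.grad)
                if p.grad is None:
                    p.grad = g
                else:
                    p.grad = p.grad + g

    def zero_grad(self):
        self.grad = None


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# convolution

# gradient recording is suspended inside no_grad() (pure-inference passes)
GRAD_ENABLED = True


class no_grad:
    """Context manager suspending tape recording (inference passes)."""

    def __enter__(self):
        global GRAD_ENABLED
        self._prev = GRAD_ENABLED
        GRAD_ENABLED = False

    def __exit__(self, *exc):
        global GRAD_ENABLED
        GRAD_ENABLED = self._prev
        return False


# The convolution is evaluated by "z-lowering": only the k z-shifted
# copies of the padded input are materialized (shape (N, Ci, k, XP, YP, Z),
# a contiguous (N, Ci*k, XP*YP*Z) matrix), and the k^2 in-plane taps
# (a, b) each contribute one full-canvas GEMM whose output is accumulated
# into the result through a shifted view.  This keeps the copied volume at
# k x the input (instead of k^3 for full im2col) while all arithmetic
# stays in BLAS — the right trade on a bandwidth-limited single CPU.

def _pad_same(x, k, dilation):
    pad = dilation * (k - 1) // 2
    if not pad:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))


def _z_lower(xp, k, dilation, Z):
    """Stack the k z-shifted views of xp: (N, Ci*k, XP*YP*Z), contiguous."""
    N, C, XP, YP, _ = xp.shape
    cz = np.empty((N, C, k, XP, YP, Z), dtype=xp.dtype)
    for c in range(k):
        cz[:, :, c] = xp[..., c * dilation:c * dilation + Z]
    return cz.reshape(N, C * k, XP * YP * Z)


def _conv3d_raw(x, w, dilation):
    """Stride-1 zero-padded "same" correlation of (N,Ci,X,Y,Z) with
    (Co,Ci,k,k,k); returns (out, padded_input)."""
    N, C, X, Y, Z = x.shape
    Co, k = w.shape[0], w.shape[-1]
    dtype = np.result_type(x.dtype, w.dtype)
    if k == 1:  # pointwise channel mixing; no padding or lowering needed
        out = np.matmul(w.reshape(Co, C), x.reshape(N, C, -1))
        return np.ascontiguousarray(out.reshape(N, Co, X, Y, Z), dtype=dtype), x
    xp = _pad_same(x, k, dilation)
    if xp.dtype != dtype:
        xp = xp.astype(dtype)
    XP, YP = xp.shape[2], xp.shape[3]
    cz = _z_lower(xp, k, dilation, Z)
    out = np.zeros((N, Co, X, Y, Z), dtype=dtype)
    canvas = np.empty((N, Co, XP * YP * Z), dtype=dtype)
    for a in range(k):
        xa = a * dilation
        for b in range(k):
            yb = b * dilation
            w2 = np.ascontiguousarray(w[:, :, a, b, :], dtype=dtype).reshape(Co, C * k)
            np.matmul(w2, cz, out=canvas)
            out += canvas.reshape(N, Co, XP, YP, Z)[:, :, xa:xa + X, yb:yb + Y, :]
    return out, xp


def _conv3d_dw(xp, g, k, dilation, w_shape):
    """Weight gradient via the same z-lowered GEMMs, with g on a padded canvas."""
    N, Co, X, Y, Z = g.shape
    Ci = w_shape[1]
    dtype = np.result_type(g.dtype, xp.dtype)
    if k == 1:
        g2 = g.reshape(N, Co, -1)
        x2 = xp.reshape(N, Ci, -1).transpose(0, 2, 1)
        return np.matmul(g2, x2).sum(axis=0).reshape(w_shape).astype(dtype)
    XP, YP = xp.shape[2], xp.shape[3]
    cz = _z_lower(xp if xp.dtype == dtype else xp.astype(dtype), k, dilation, Z)
    czt = cz.transpose(0, 2, 1)
    gp = np.zeros((N, Co, XP, YP, Z), dtype=dtype)
    dw = np.empty(w_shape, dtype=dtype)
    for a in range(k):
        xa = a * dilation
        for b in range(k):
            yb = b * dilation
            gp.fill(0.0)
            gp[:, :, xa:xa + X, yb:yb + Y, :] = g
            prod = np.matmul(gp.reshape(N, Co, -1), czt).sum(axis=0)
            dw[:, :, a, b, :] = prod.reshape(Co, Ci, k)
    return dw


def conv3d(x, weight, dilation=1, bias=None):
    """3D convolution, stride 1, zero-padded to preserve spatial shape.

    x: (N, Cin, X, Y, Z); weight: (Cout, Cin, k, k, k) with odd k;
    bias: (Cout,) or None.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    k = weight.data.shape[-1]
    if k % 2 != 1:
        raise ValueError("kernel edge must be odd")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    if x.data.shape[1] != weight.data.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]}, "
            f"kernel expects {weight.data.shape[1]}"
        )
    out, xp = _conv3d_raw(x.data, weight.data, dilation)
    if bias is not None:
        bias = _as_tensor(bias)
        out += bias.data.reshape(1, -1, 1, 1, 1)
    if not GRAD_ENABLED:
        return Tensor(out)

    def grad_x(g):
        # data gradient = same-conv of g with flipped, channel-transposed kernel
        wt = weight.data.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        gx, _ = _conv3d_raw(g, np.ascontiguousarray(wt), dilation)
        return gx

    def grad_w(g):
        return _conv3d_dw(xp, g, k, dilation, weight.data.shape)

    parents = [(x, grad_x), (weight, grad_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3, 4))))
    return Tensor(out, parents=tuple(parents))


# ---------------------------------------------------------------------------
# batch normalization

def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.1, eps=1e-5, update_running=None):
    """Per-channel batch normalization over (N, C, X, Y, Z).

    `running_mean`/`running_var` are plain numpy arrays updated in place
    during training (biased variance, exponential momentum).  Pass
    `update_running=False` to normalize with batch statistics without
    touching the running estimates (auxiliary forward passes).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    if update_running is None:
        update_running = training
    axes = (0, 2, 3, 4)
    cshape = (1, -1, 1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        if update_running:
            running_mean *= 1.0 - momentum
            running_mean += momentum * mu
            running_var *= 1.0 - momentum
            running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(cshape)) * ivar.reshape(cshape)
    out = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

    m = x.data.size // x.data.shape[1]  # elements per channel

    def grad_x(g):
        if not training:
            return g * (gamma.data * ivar).reshape(cshape)
        dxhat = g * gamma.data.reshape(cshape)
        s1 = dxhat.sum(axis=axes).reshape(cshape)
        s2 = (dxhat * xhat).sum(axis=axes).reshape(cshape)
        return ivar.reshape(cshape) * (dxhat - s1 / m - xhat * s2 / m)

    parents = (
        (x, grad_x),
        (gamma, lambda g: (g * xhat).sum(axis=axes)),
        (beta, lambda g: g.sum(axis=axes)),
    )
    return Tensor(out, parents=parents)


# ---------------------------------------------------------------------------
# pointwise ops

def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    return Tensor(x.data * mask, parents=((x, lambda g: g * mask),))


def sigmoid(x):
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(s, parents=((x, lambda g: g * s * (1.0 - s)),))


def add(x, y):
    x, y = _as_tensor(x), _as_tensor(y)
    return Tensor(
        x.data + y.data,
        parents=(
            (x, lambda g: _unbroadcast(g, x.data.shape)),
            (y, lambda g: _unbroadcast(g, y.data.shape)),
        ),
    )


def mul(x, y):
    x, y = _as_tensor(x), _as_tensor(y)
    return Tensor(
        x.data * y.data,
        parents=(
            (x, lambda g: _unbroadcast(g * y.data, x.data.shape)),
            (y, lambda g: _unbroadcast(g * x.data, y.data.shape)),
        ),
    )


def reduce_sum(x):
    """Sum of all elements, as a scalar Tensor."""
    x = _as_tensor(x)
    return Tensor(
        np.asarray(x.data.sum()),
        parents=((x, lambda g: np.broadcast_to(g, x.data.shape).copy()),),
    )


def global_avg_pool(x):
    """Mean over the three spatial axes; output shape (N, C, 1, 1, 1)."""
    x = _as_tensor(x)
    n = x.data.shape[2] * x.data.shape[3] * x.data.shape[4]
    out = x.data.mean(axis=(2, 3, 4), keepdims=True)

    def grad(g):
        return np.broadcast_to(g / n, x.data.shape).copy()

    return Tensor(out, parents=((x, grad),))


# ---------------------------------------------------------------------------
# classification head

def softmax(logits, axis=1):
    """Plain numpy softmax (inference path, no gradient)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean voxel-wise categorical cross-entropy.

    logits: Tensor (N, C, X, Y, Z); labels: integer array (N, X, Y, Z).
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sez = ez.sum(axis=1, keepdims=True)
    logp = z - np.log(sez)
    lab = labels[:, None]
    picked = np.take_along_axis(logp, lab, axis=1)
    n = picked.size
    loss = -picked.sum() / n

    def grad(g):
        gsoft = ez / sez
        idx = np.ogrid[tuple(slice(s) for s in labels.shape)]
        gsoft[idx[0], labels, idx[1], idx[2], idx[3]] -= 1.0
        return gsoft * (g / n)

    return Tensor(np.asarray(loss), parents=((logits, grad),))


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with externally supplied learning rate (poly-decayed by the caller)."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
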