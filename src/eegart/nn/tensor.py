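"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape: every operation returns a new :class:`Tensor` holding the
result, its parent tensors and a closure computing the parents' gradients
from the output gradient.  ``Tensor.backward()`` walks the tape in reverse
topological order and accumulates ``.grad`` on every tensor that requires
it.  Only the operations the artifact-detection network needs are provided;
each is vectorised over a leading batch axis and preserves the input dtype
(float32 in production, float64 in gradient-check tests).

Memory-critical operations (multi-head self-attention) do not retain their
quadratic intermediates; they recompute attention weights during the
backward pass so sequence lengths in the thousands stay within a few
hundred megabytes.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward_fn = backward_fn

    # -- conveniences -------------------------------------------------
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
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def item(self):
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(())[()])

    def detach(self):
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    # -- autodiff -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar output")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            grads = node._backward_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g
            # free the closure and output gradient of interior nodes early
            if node is not self:
                node._backward_fn = None
                if node._parents:
                    node.grad = None
            node._parents = ()


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn):
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, True, tuple(parents), backward_fn)
    return Tensor(data)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------
# elementwise / linear algebra
# ---------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(out, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return _unbroadcast(g * b.data, a.data.shape), _unbroadcast(g * a.data, b.data.shape)

    return _make(out, (a, b), backward)


def scale(a, c: float):
    a = _as_tensor(a)
    out = a.data * c

    def backward(g):
        return (g * c,)

    return _make(out, (a,), backward)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _make(out, (a, b), backward)


def linear(x, w, b):
    """``x @ w + b`` with ``w`` of shape (fan_in, fan_out)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    out = x.data @ w.data + b.data

    def backward(g):
        gx = g @ w.data.T
        x2 = x.data.reshape(-1, x.data.shape[-1])
        g2 = g.reshape(-1, g.shape[-1])
        gw = x2.T @ g2
        gb = g2.sum(axis=0)
        return gx, gw, gb

    return _make(out, (x, w, b), backward)


def reshape(x, shape):
    x = _as_tensor(x)
    old = x.data.shape
    out = x.data.reshape(shape)

    def backward(g):
        return (g.reshape(old),)

    return _make(out, (x,), backward)


def transpose(x, axes):
    x = _as_tensor(x)
    out = np.transpose(x.data, axes)
    inv = np.argsort(axes)

    def backward(g):
        return (np.transpose(g, inv),)

    return _make(out, (x,), backward)


def concat(tensors, axis):
    tensors = [_as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(tensors), backward)


def mean(x, axis, keepdims=False):
    x = _as_tensor(x)
    out = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size / out.size

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.data.shape).astype(x.data.dtype) / n,)

    return _make(out, (x,), backward)


def elu(x, alpha=1.0):
    x = _as_tensor(x)
    neg = alpha * np.expm1(np.minimum(x.data, 0.0))
    out = np.where(x.data > 0, x.data, neg).astype(x.data.dtype)

    def backward(g):
        return (np.where(x.data > 0, g, g * (neg + alpha)),)

    return _make(out, (x,), backward)


def softmax(x, axis=-1):
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=axis, keepdims=True)
        return (p * (g - dot),)

    return _make(p, (x,), backward)


def dropout(x, p, rng, training):
    """Inverted dropout; identity when not training or p == 0."""
    x = _as_tensor(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = x.data * keep

    def backward(g):
        return (g * keep,)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------

def layer_norm(x, gamma, beta, eps=1e-5):
    """Normalise over the last axis."""
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        gg = g * gamma.data
        m1 = gg.mean(axis=-1, keepdims=True)
        m2 = (gg * xhat).mean(axis=-1, keepdims=True)
        gx = inv * (gg - m1 - xhat * m2)
        axes = tuple(range(g.ndim - 1))
        return gx.astype(x.data.dtype), (g * xhat).sum(axis=axes), g.sum(axis=axes)

    return _make(out, (x, gamma, beta), backward)


def batch_norm(x, gamma, beta, running_mean, running_var, training, momentum=0.1, eps=1e-5):
    """Channel-wise batch normalisation; channel axis is 1.

    ``running_mean``/``running_var`` are plain numpy arrays updated in place
    when ``training`` is true.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0,) + tuple(range(2, x.data.ndim))
    shape = (1, -1) + (1,) * (x.data.ndim - 2)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mu = running_mean.astype(x.data.dtype)
        var = running_var.astype(x.data.dtype)
    inv = (1.0 / np.sqrt(var + eps)).reshape(shape).astype(x.data.dtype)
    xhat = (x.data - mu.reshape(shape)) * inv
    out = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)

    def backward(g):
        gg = g * gamma.data.reshape(shape)
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        if training:
            m1 = gg.mean(axis=axes, keepdims=True)
            m2 = (gg * xhat).mean(axis=axes, keepdims=True)
            gx = inv * (gg - m1 - xhat * m2)
        else:
            gx = inv * gg
        return gx.astype(x.data.dtype), dgamma, dbeta

    return _make(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------

def conv1d(x, w, b, stride=1):
    """1-D convolution, no padding.  x: (B,C,L), w: (O,C,K), b: (O,)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, C, L = x.data.shape
    O, _, K = w.data.shape
    Lout = (L - K) // stride + 1
    if Lout < 1:
        raise ValueError(f"conv1d: input length {L} shorter than kernel {K}")
    cols = np.empty((B, C, K, Lout), dtype=x.data.dtype)
    for j in range(K):
        cols[:, :, j, :] = x.data[:, :, j : j + stride * Lout : stride]
    cols2 = cols.reshape(B, C * K, Lout)
    w2 = w.data.reshape(O, C * K)
    out = np.matmul(w2, cols2) + b.data[:, None]

    def backward(g):
        gw = np.einsum("bol,bkl->ok", g, cols2, optimize=True).reshape(w.data.shape)
        gb = g.sum(axis=(0, 2))
        gcols = np.matmul(w2.T, g).reshape(B, C, K, Lout)
        gx = np.zeros_like(x.data)
        for j in range(K):
            gx[:, :, j : j + stride * Lout : stride] += gcols[:, :, j, :]
        return gx, gw, gb

    return _make(out, (x, w, b), backward)


def conv2d(x, w, b, stride=1, pad_w=0):
    """2-D convolution, stride 1, optional zero padding along the width axis.

    x: (B,C,H,W), w: (O,C,KH,KW), b: (O,).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    if stride != 1:
        raise NotImplementedError("only stride 1 is used")
    xd = x.data
    if pad_w:
        xd = np.pad(xd, ((0, 0), (0, 0), (0, 0), (pad_w, pad_w)))
    B, C, H, W = xd.shape
    O, _, KH, KW = w.data.shape
    Hout, Wout = H - KH + 1, W - KW + 1
    if Hout < 1 or Wout < 1:
        raise ValueError(f"conv2d: input {x.data.shape[2:]} too small for kernel ({KH},{KW})")
    out = np.zeros((B, O, Hout, Wout), dtype=xd.dtype)
    for i in range(KH):
        for j in range(KW):
            out += np.einsum(
                "oc,bchw->bohw", w.data[:, :, i, j], xd[:, :, i : i + Hout, j : j + Wout],
                optimize=True,
            )
    out += b.data[None, :, None, None]

    def backward(g):
        gw = np.empty_like(w.data)
        gx_pad = np.zeros_like(xd)
        for i in range(KH):
            for j in range(KW):
                patch = xd[:, :, i : i + Hout, j : j + Wout]
                gw[:, :, i, j] = np.einsum("bohw,bchw->oc", g, patch, optimize=True)
                gx_pad[:, :, i : i + Hout, j : j + Wout] += np.einsum(
                    "oc,bohw->bchw", w.data[:, :, i, j], g, optimize=True
                )
        gb = g.sum(axis=(0, 2, 3))
        gx = gx_pad[:, :, :, pad_w : gx_pad.shape[3] - pad_w] if pad_w else gx_pad
        return gx, gw, gb

    return _make(out, (x, w, b), backward)


def max_pool1d(x, kernel, stride):
    x = _as_tensor(x)
    B, C, L = x.data.shape
    Lout = (L - kernel) // stride + 1
    if Lout < 1:
        raise ValueError(f"max_pool1d: input length {L} shorter than kernel {kernel}")
    win = np.empty((B, C, kernel, Lout), dtype=x.data.dtype)
    for j in range(kernel):
        win[:, :, j, :] = x.data[:, :, j : j + stride * Lout : stride]
    arg = win.argmax(axis=2)
    out = np.take_along_axis(win, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(g):
        gx = np.zeros_like(x.data)
        for j in range(kernel):
            gx[:, :, j : j + stride * Lout : stride] += g * (arg == j)
        return (gx,)

    return _make(out, (x,), backward)


def max_pool2d(x, kernel, stride=1):
    """2-D max pooling; ``kernel`` is (kh, kw), stride 1."""
    x = _as_tensor(x)
    if stride != 1:
        raise NotImplementedError("only stride 1 is used")
    kh, kw = kernel
    B, C, H, W = x.data.shape
    Hout, Wout = H - kh + 1, W - kw + 1
    if Hout < 1 or Wout < 1:
        raise ValueError(f"max_pool2d: input {x.data.shape[2:]} too small for kernel {kernel}")
    win = np.empty((B, C, kh * kw, Hout, Wout), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            win[:, :, i * kw + j, :, :] = x.data[:, :, i : i + Hout, j : j + Wout]
    arg = win.argmax(axis=2)
    out = np.take_along_axis(win, arg[:, :, None, :, :], axis=2)[:, :, 0, :, :]

    def backward(g):
        gx = np.zeros_like(x.data)
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i : i + Hout, j : j + Wout] += g * (arg == i * kw + j)
        return (gx,)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------

_ATTN_WORKSPACE: dict = {}

#: per-layer byte budget under which attention weights are kept for the
#: backward pass instead of being recomputed (speed/memory trade-off)
ATTENTION_CACHE_BYTES = 400 * 1024 * 1024

_P_POOL: dict = {}


def _pool_take(shape, dtype):
    """Reusable attention-weight cache arrays (avoids per-step page faults)."""
    key = (shape, np.dtype(dtype).str)
    free = _P_POOL.get(key)
    if free:
        return free.pop()
    if sum(len(v) for v in _P_POOL.values()) > 8:
        _P_POOL.clear()
    return np.empty(shape, dtype=dtype)


def _pool_give(arr):
    key = (arr.shape, arr.dtype.str)
    free = _P_POOL.setdefault(key, [])
    if len(free) < 8:
        free.append(arr)


def _attn_buffers(shape, dtype, n=2):
    """Reusable (B,T,T) scratch arrays; avoids ~70 MB allocations per head."""
    key = (shape, np.dtype(dtype).str, n)
    if key not in _ATTN_WORKSPACE:
        if len(_ATTN_WORKSPACE) >= 3:
            _ATTN_WORKSPACE.clear()
        _ATTN_WORKSPACE[key] = [np.empty(shape, dtype=dtype) for _ in range(n)]
    return _ATTN_WORKSPACE[key]


def _softmax_inplace(s, mx, tot):
    np.max(s, axis=-1, keepdims=True, out=mx)
    np.subtract(s, mx, out=s)
    np.exp(s, out=s)
    np.sum(s, axis=-1, keepdims=True, out=tot)
    np.divide(s, tot, out=s)


def multi_head_self_attention(x, w_qkv, b_qkv, w_out, b_out, num_heads):
    """Scaled dot-product multi-head self-attention, softmax(QK^T/sqrt(d_k))V.

    x: (B,T,D); w_qkv: (D,3D); w_out: (D,D).  The (T,T) attention matrices
    live in a shared scratch buffer, are discarded after the forward pass
    and recomputed head-by-head during backpropagation, so peak memory
    stays O(B*T*T) for a single head regardless of depth.  The 1/sqrt(d_k)
    scale is folded into Q before the score matmul.
    """
    x, w_qkv, b_qkv = _as_tensor(x), _as_tensor(w_qkv), _as_tensor(b_qkv)
    w_out, b_out = _as_tensor(w_out), _as_tensor(b_out)
    B, T, D = x.data.shape
    if D % num_heads:
        raise ValueError(f"d_model {D} not divisible by {num_heads} heads")
    dk = D // num_heads
    scale_f = np.asarray(1.0 / np.sqrt(dk), dtype=x.data.dtype)

    qkv = x.data @ w_qkv.data + b_qkv.data          # (B,T,3D)
    q, k, v = np.split(qkv, 3, axis=-1)

    def heads(a):
        # (B,T,D) -> (B,h,T,dk), contiguous so per-head matmuls hit BLAS fast paths
        return np.ascontiguousarray(a.reshape(B, T, num_heads, dk).transpose(0, 2, 1, 3))

    qh, kh, vh = heads(q * scale_f), heads(k), heads(v)
    khT = np.ascontiguousarray(kh.transpose(0, 1, 3, 2))
    mx = np.empty((B, T, 1), dtype=x.data.dtype)
    tot = np.empty((B, T, 1), dtype=x.data.dtype)
    needs_grad = _GRAD_ENABLED and any(
        t.requires_grad for t in (x, w_qkv, b_qkv, w_out, b_out))
    cache_p = needs_grad and (
        num_heads * B * T * T * x.data.itemsize <= ATTENTION_CACHE_BYTES)
    p_cache = _pool_take((num_heads, B, T, T), x.data.dtype) if cache_p else None
    (s_buf, _) = _attn_buffers((B, T, T), x.data.dtype)
    oh = np.empty_like(qh)
    for h in range(num_heads):
        p = p_cache[h] if cache_p else s_buf
        np.matmul(qh[:, h], khT[:, h], out=p)
        _softmax_inplace(p, mx, tot)
        np.matmul(p, vh[:, h], out=oh[:, h])
    o = oh.transpose(0, 2, 1, 3).reshape(B, T, D)
    out = o @ w_out.data + b_out.data

    def backward(g):
        g2 = g.reshape(-1, D)
        gw_out = o.reshape(-1, D).T @ g2
        gb_out = g2.sum(axis=0)
        go = np.ascontiguousarray(
            (g @ w_out.data.T).reshape(B, T, num_heads, dk).transpose(0, 2, 1, 3)
        )
        gq = np.empty_like(qh)
        gk = np.empty_like(kh)
        gv = np.empty_like(vh)
        s_buf, g_buf = _attn_buffers((B, T, T), x.data.dtype)
        rowdot = np.empty((B, T), dtype=x.data.dtype)
        for h in range(num_heads):
            if cache_p:
                p = p_cache[h]
            else:
                p = s_buf                                      # P, recomputed
                np.matmul(qh[:, h], khT[:, h], out=p)
                _softmax_inplace(p, mx, tot)
            np.matmul(go[:, h], vh[:, h].transpose(0, 2, 1), out=g_buf)   # dP
            np.matmul(p.transpose(0, 2, 1), go[:, h], out=gv[:, h])
            np.einsum("btc,btc->bt", g_buf, p, out=rowdot, optimize=True)
            np.subtract(g_buf, rowdot[:, :, None], out=g_buf)
            np.multiply(g_buf, p, out=g_buf)                   # dS (pre-scale)
            np.matmul(g_buf, kh[:, h], out=gq[:, h])           # dS @ k
            # qh already carries the 1/sqrt(d_k) factor, so this is dK exactly
            np.matmul(g_buf.transpose(0, 2, 1), qh[:, h], out=gk[:, h])
        gq *= scale_f  # dQ = scale * (dS @ K)
        if cache_p:
            _pool_give(p_cache)

        def merge(a):
            return a.transpose(0, 2, 1, 3).reshape(B, T, D)

        gqkv = np.concatenate([merge(gq), merge(gk), merge(gv)], axis=-1)
        gqkv2 = gqkv.reshape(-1, 3 * D)
        gw_qkv = x.data.reshape(-1, D).T @ gqkv2
        gb_qkv = gqkv2.sum(axis=0)
        gx = gqkv @ w_qkv.data.T
        return gx, gw_qkv, gb_qkv, gw_out, gb_out

    return _make(out, (x, w_qkv, b_qkv, w_out, b_out), backward)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

def softmax_cross_entropy(logits, targets):
    """Mean cross-entropy between softmax(logits) and integer ``targets``.

    Probabilities are clamped to 1e-12 before the log.
    """
    logits = _as_tensor(logits)
    y = np.asarray(targets)
    B = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    picked = np.clip(p[np.arange(B), y], 1e-12, 1.0)
    out = np.asarray(-np.log(picked).mean(), dtype=logits.data.dtype)

    def backward(g):
        gl = p.copy()
        gl[np.arange(B), y] -= 1.0
        return (gl * (g / B),)

    return _make(out, (logits,), backward)


def stable_softmax(z):
    """Plain numpy softmax along the last axis (no autodiff)."""
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
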