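"""Trainable layers built on the autodiff tape.

Weight matrices use fan-in-scaled uniform initialisation,
U(-1/sqrt(fan_in), +1/sqrt(fan_in)); biases start at zero so a zero input
propagates to zero activations (and hence uniform class probabilities)
through a freshly initialised network in inference mode.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import tensor as T
from .tensor import Tensor


def _uniform(rng, shape, fan_in, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(dtype), requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield attr
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        out = OrderedDict()
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor) and attr.requires_grad:
                out[key] = attr
            elif isinstance(attr, Module):
                out.update(attr.named_parameters(f"{key}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self):
        return list(self.named_parameters().values())

    def num_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode=True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- persistence --------------------------------------------------
    def _named_buffers(self, prefix=""):
        out = OrderedDict()
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Module):
                out.update(attr._named_buffers(f"{key}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.update(item._named_buffers(f"{key}.{i}."))
            elif isinstance(attr, np.ndarray) and name.startswith("running_"):
                out[key] = attr
        return out

    def state_dict(self):
        state = OrderedDict((k, v.data.copy()) for k, v in self.named_parameters().items())
        state.update((k, v.copy()) for k, v in self._named_buffers().items())
        return state

    def load_state_dict(self, state):
        params = self.named_parameters()
        buffers = self._named_buffers()
        missing = (set(params) | set(buffers)) - set(state)
        extra = set(state) - (set(params) | set(buffers))
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(p.data.dtype).copy()
        for k, b in buffers.items():
            b[...] = state[k]


class Linear(Module):
    def __init__(self, fan_in, fan_out, rng, dtype=T.DEFAULT_DTYPE):
        super().__init__()
        self.weight = _uniform(rng, (fan_in, fan_out), fan_in, dtype)
        self.bias = Tensor(np.zeros(fan_out, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return T.linear(x, self.weight, self.bias)


class Conv1d(Module):
    def __init__(self, c_in, c_out, kernel, stride, rng, dtype=T.DEFAULT_DTYPE):
        super().__init__()
        self.stride = stride
        self.weight = _uniform(rng, (c_out, c_in, kernel), c_in * kernel, dtype)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return T.conv1d(x, self.weight, self.bias, self.stride)


class Conv2d(Module):
    """Stride-1 2-D convolution; ``pad_time_same`` zero-pads the width
    (time-frame) axis so short spectrograms keep their frame count."""

    def __init__(self, c_in, c_out, kernel, rng, pad_time_same=False, dtype=T.DEFAULT_DTYPE):
        super().__init__()
        kh, kw = kernel
        self.kernel = kernel
        self.pad_time_same = pad_time_same
        self.weight = _uniform(rng, (c_out, c_in, kh, kw), c_in * kh * kw, dtype)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        pad_w = (self.kernel[1] - 1) // 2 if self.pad_time_same else 0
        return T.conv2d(x, self.weight, self.bias, pad_w=pad_w)


class BatchNorm(Module):
    """Channel-wise batch normalisation (channel axis 1, any rank)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=T.DEFAULT_DTYPE):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x):
        return T.batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class LayerNorm(Module):
    def __init__(self, width, eps=1e-5, dtype=T.DEFAULT_DTYPE):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(width, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(width, dtype=dtype), requires_grad=True)

    def __call__(self, x):
        return T.layer_norm(x, self.gamma, self.beta, self.eps)


class ELU(Module):
    def __call__(self, x):
        return T.elu(x)


class MaxPool1d(Module):
    def __init__(self, kernel, stride):
        super().__init__()
        self.kernel, self.stride = kernel, stride

    def __call__(self, x):
        return T.max_pool1d(x, self.kernel, self.stride)


class MaxPool2d(Module):
    """(kh, kw) stride-1 max pooling; ``clamp`` shrinks the kernel on an
    axis whose extent is smaller than the kernel (needed only for 1-frame
    spectrograms from 1 s segments)."""

    def __init__(self, kernel, clamp=False):
        super().__init__()
        self.kernel = kernel
        self.clamp = clamp

    def __call__(self, x):
        kh, kw = self.kernel
        if self.clamp:
            kh = min(kh, x.shape[2])
            kw = min(kw, x.shape[3])
        return T.max_pool2d(x, (kh, kw))


class Dropout(Module):
    """Inverted dropout drawing from the generator installed on the layer
    (the trainer reseeds it, keeping runs reproducible)."""

    def __init__(self, p):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)

    def __call__(self, x):
        return T.dropout(x, self.p, self.rng, self.training)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder layer: x + MHSA(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, d_model, num_heads, ffn_width, rng, dtype=T.DEFAULT_DTYPE):
        super().__init__()
        self.num_heads = num_heads
        self.ln1 = LayerNorm(d_model, dtype=dtype)
        self.w_qkv = _uniform(rng, (d_model, 3 * d_model), d_model, dtype)
        self.b_qkv = Tensor(np.zeros(3 * d_model, dtype=dtype), requires_grad=True)
        self.w_out = _uniform(rng, (d_model, d_model), d_model, dtype)
        self.b_out = Tensor(np.zeros(d_model, dtype=dtype), requires_grad=True)
        self.ln2 = LayerNorm(d_model, dtype=dtype)
        self.ffn1 = Linear(d_model, ffn_width, rng, dtype)
        self.ffn2 = Linear(ffn_width, d_model, rng, dtype)

    def __call__(self, x):
        att = T.multi_head_self_attention(
            self.ln1(x), self.w_qkv, self.b_qkv, self.w_out, self.b_out, self.num_heads
        )
        x = T.add(x, att)
        h = self.ffn2(T.elu(self.ffn1(self.ln2(x))))
        return T.add(x, h)

    def attention_probs(self, x):
        """(B, heads, T, T) attention weights for inspection (no autodiff)."""
        xn = self.ln1(x if isinstance(x, Tensor) else Tensor(x)).data
        B, T_len, D = xn.shape
        dk = D // self.num_heads
        qkv = xn @ self.w_qkv.data + self.b_qkv.data
        q, k, _ = np.split(qkv, 3, axis=-1)
        q = q.reshape(B, T_len, self.num_heads, dk).transpose(0, 2, 1, 3)
        k = k.reshape(B, T_len, self.num_heads, dk).transpose(0, 2, 1, 3)
        s = np.matmul(q, k.transpose(0, 1, 3, 2)) / np.sqrt(dk)
        s -= s.max(axis=-1, keepdims=True)
        np.exp(s, out=s)
        s /= s.sum(axis=-1, keepdims=True)
        return s


class TransformerEncoder(Module):
    """Stack of pre-norm self-attention layers with a closing LayerNorm.

    With no positional encoding the encoder is permutation-equivariant over
    the sequence axis.  Sinusoidal encodings can be switched on when the
    token order should matter.
    """

    def __init__(self, num_layers, d_model, num_heads, ffn_width, rng,
                 positional_encoding="none", dtype=T.DEFAULT_DTYPE):
        super().__init__()
        if d_model % num_heads:
            raise ValueError(f"d_model={d_model} not divisible by num_heads={num_heads}")
        self.positional_encoding = positional_encoding
        self.d_model = d_model
        self.layers = [
            TransformerEncoderLayer(d_model, num_heads, ffn_width, rng, dtype)
            for _ in range(num_layers)
        ]
        self.final_ln = LayerNorm(d_model, dtype=dtype)

    def _sinusoid(self, T_len, dtype):
        pos = np.arange(T_len)[:, None]
        i = np.arange(self.d_model)[None, :]
        angles = pos / np.power(10000.0, (2 * (i // 2)) / self.d_model)
        enc = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
        return enc.astype(dtype)

    def __call__(self, x):
        if x.shape[-1] != self.d_model:
            raise ValueError(f"expected embedding width {self.d_model}, got {x.shape[-1]}")
        if self.positional_encoding == "sinusoidal":
            x = T.add(x, Tensor(self._sinusoid(x.shape[1], x.dtype)))
        for layer in self.layers:
            x = layer(x)
        return self.final_ln(x)
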