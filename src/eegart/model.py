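"""The dual-branch local/global feature-fusion classifier.

Architecture
------------
Two parallel branches process each 1-D EEG segment:

* time branch: Conv(1->16, k=8, s=4) -> BN -> ELU -> MaxPool(4,2) ->
  Conv(16->40, k=4, s=2) -> BN -> ELU -> MaxPool(2,1), transposed to a
  T x 40 token sequence (shallow local features F_a); a 6-layer, 5-head
  transformer encoder yields global features F_tr; a Conv(40->40, k=3)
  over F_tr yields deep local features F_b.
* time-frequency branch: the segment's 126 x F log-magnitude STFT goes
  through Conv(1->16, k=(1,3)) -> BN -> ELU -> MaxPool(2,2) ->
  Conv(16->40, k=(3,1)) -> BN -> ELU -> MaxPool(2,2) (all stride 1),
  is flattened row-major over (Hout, Wout) to a (Hout*Wout) x 40 sequence,
  encoded by a second transformer, and refined by a Conv2d(40->40, (3,3))
  after unflattening.

Each domain concatenates its shallow/global/deep sequences along the token
axis and mixes channels with a kernel-1 convolution; the two domain feature
sets are concatenated (time domain first) and classified by two fully
connected layers with a softmax output.  Ablation variants prune stages;
alternative fusion strategies replace concatenation with an MLP-gated
weighted sum of pooled features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import tensor as T
from .tfr import stft_spectrogram

VARIANTS = ("cnn", "cnn_tf", "cnn_tf_fusion", "cnn_tf_cnn_fusion", "full")
FUSION_STRATEGIES = ("concat_cnn", "weighted", "weighted_cnn")


@dataclass
class TransformerConfig:
    """Shared shape of both branch encoders (weights are separate)."""

    num_layers: int = 6
    num_heads: int = 5
    d_model: int = 40
    ffn_width: int = 160
    positional_encoding: str = "none"

    def __post_init__(self):
        if self.d_model % self.num_heads:
            raise ValueError(f"d_model={self.d_model} must be divisible by num_heads={self.num_heads}")
        if self.positional_encoding not in ("none", "sinusoidal"):
            raise ValueError(f"unknown positional_encoding {self.positional_encoding!r}")

    @property
    def d_k(self) -> int:
        return self.d_model // self.num_heads


@dataclass
class ModelConfig:
    """Every architectural hyperparameter of the reference configuration."""

    segment_seconds: float = 4.0
    fs: float = 250.0
    num_classes: int = 6
    embed_dim: int = 40
    stft_window: int = 250
    stft_overlap: int = 200
    stft_log: bool = True
    table_kernel_order: bool = True  # (1,3) conv first, then (3,1)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    fusion_strategy: str = "concat_cnn"
    variant: str = "full"
    classifier_hidden: int = 128
    dropout: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.transformer, dict):
            self.transformer = TransformerConfig(**self.transformer)
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.fusion_strategy not in FUSION_STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.fusion_strategy!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if self.embed_dim != self.transformer.d_model:
            raise ValueError("embed_dim must equal transformer.d_model")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_seconds * self.fs))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------
# shape arithmetic (single source of truth for layer sizing; the test
# suite re-derives these with an independent floor-arithmetic oracle)
# ---------------------------------------------------------------------

def _conv_len(length, kernel, stride):
    out = (length - kernel) // stride + 1
    if out < 1:
        raise ValueError(f"extent {length} too small for kernel {kernel} (stride {stride})")
    return out


def time_branch_length(segment_samples: int) -> int:
    """Token count T after the 1-D conv stack."""
    l = _conv_len(segment_samples, 8, 4)
    l = _conv_len(l, 4, 2)      # max-pool 4, stride 2
    l = _conv_len(l, 4, 2)      # conv 4, stride 2
    l = _conv_len(l, 2, 1)      # max-pool 2, stride 1
    return l


def spectrogram_shape(segment_samples: int, window: int = 250, overlap: int = 200):
    hop = window - overlap
    if segment_samples < window:
        raise ValueError(f"segment ({segment_samples}) shorter than STFT window ({window})")
    return window // 2 + 1, (segment_samples - window) // hop + 1


def _pool_len(length, kernel):
    """Stride-1 max pool with kernel clamped to the available extent."""
    return _conv_len(length, min(kernel, length), 1)


def tf_branch_dims(bins: int, frames: int):
    """(Hout, Wout) after the 2-D conv stack, plus the padding rule flag.

    When frames < 5 the time (frame) axis cannot survive two unpadded
    width-3 kernels, so 2-D convolutions use "same" zero padding along the
    time axis only; pooling kernels clamp to the available extent.
    """
    pad_time = frames < 5
    h, w = bins, frames
    # conv (1,3) then conv (3,1) (table order; the transposed order gives
    # identical output dims since the ops commute dimension-wise)
    w = w if pad_time else _conv_len(w, 3, 1)
    h, w = _pool_len(h, 2), _pool_len(w, 2)
    h = _conv_len(h, 3, 1)
    h, w = _pool_len(h, 2), _pool_len(w, 2)
    return h, w, pad_time


def shape_plan(cfg: ModelConfig) -> dict:
    """All sequence lengths of the forward pass, by pure arithmetic."""
    L = cfg.segment_samples
    t = time_branch_length(L)
    t1 = t - 2
    plan = {"L": L, "T": t, "T1": t1}
    if cfg.variant == "full":
        bins, frames = spectrogram_shape(L, cfg.stft_window, cfg.stft_overlap)
        h, w, pad_time = tf_branch_dims(bins, frames)
        t2 = (h - 2) * (w if pad_time else w - 2)
        plan.update({"bins": bins, "frames": frames, "Hout": h, "Wout": w,
                     "HW": h * w, "T2": t2, "pad_time": pad_time})
        plan["T4"] = 2 * h * w + t2
    plan["T3"] = 2 * t + t1
    seq_len = {
        "cnn": t,
        "cnn_tf": t,
        "cnn_tf_fusion": 2 * t,
        "cnn_tf_cnn_fusion": plan["T3"],
        "full": plan["T3"] + plan.get("T4", 0),
    }[cfg.variant]
    if cfg.fusion_strategy != "concat_cnn" and cfg.variant in ("cnn_tf_cnn_fusion", "full"):
        per_domain = 1 if cfg.fusion_strategy == "weighted" else 3
        seq_len = per_domain * (2 if cfg.variant == "full" else 1)
    plan["seq_len"] = seq_len
    plan["flat_width"] = seq_len * cfg.embed_dim
    return plan


# ---------------------------------------------------------------------
# sub-modules
# ---------------------------------------------------------------------

class TimeConvStack(nn.Module):
    """CONV1Da: shallow local features from the raw waveform."""

    def __init__(self, n, rng):
        super().__init__()
        self.conv1 = nn.Conv1d(1, 16, 8, 4, rng)
        self.bn1 = nn.BatchNorm(16)
        self.conv2 = nn.Conv1d(16, n, 4, 2, rng)
        self.bn2 = nn.BatchNorm(n)

    def __call__(self, x):
        h = T.max_pool1d(T.elu(self.bn1(self.conv1(x))), 4, 2)
        h = T.max_pool1d(T.elu(self.bn2(self.conv2(h))), 2, 1)
        return T.transpose(h, (0, 2, 1))  # (B, T, n)


class SpecConvStack(nn.Module):
    """CONV2Da: shallow local features from the spectrogram."""

    def __init__(self, n, rng, pad_time=False, table_order=True):
        super().__init__()
        k_first, k_second = ((1, 3), (3, 1)) if table_order else ((3, 1), (1, 3))
        self.conv1 = nn.Conv2d(1, 16, k_first, rng, pad_time_same=pad_time)
        self.bn1 = nn.BatchNorm(16)
        self.pool1 = nn.MaxPool2d((2, 2), clamp=True)
        self.conv2 = nn.Conv2d(16, n, k_second, rng, pad_time_same=pad_time)
        self.bn2 = nn.BatchNorm(n)
        self.pool2 = nn.MaxPool2d((2, 2), clamp=True)

    def __call__(self, x):
        h = self.pool1(T.elu(self.bn1(self.conv1(x))))
        h = self.pool2(T.elu(self.bn2(self.conv2(h))))
        return h  # (B, n, Hout, Wout)


class DeepConv1d(nn.Module):
    """CONV1Db: deep local features from the transformer output."""

    def __init__(self, n, rng):
        super().__init__()
        self.conv = nn.Conv1d(n, n, 3, 1, rng)
        self.bn = nn.BatchNorm(n)

    def __call__(self, seq):  # (B, T, n) -> (B, T-2, n)
        h = T.transpose(seq, (0, 2, 1))
        h = T.elu(self.bn(self.conv(h)))
        return T.transpose(h, (0, 2, 1))


class DeepConv2d(nn.Module):
    """CONV2Db: deep local features after unflattening to (n, H, W)."""

    def __init__(self, n, rng, pad_time=False):
        super().__init__()
        self.conv = nn.Conv2d(n, n, (3, 3), rng, pad_time_same=pad_time)
        self.bn = nn.BatchNorm(n)

    def __call__(self, seq, hout, wout):
        b, hw, n = seq.shape
        if hw != hout * wout:
            raise ValueError(f"sequence length {hw} does not match Hout*Wout = {hout}*{wout}")
        grid = T.reshape(T.transpose(seq, (0, 2, 1)), (b, n, hout, wout))
        h = T.elu(self.bn(self.conv(grid)))
        b2, n2, h2, w2 = h.shape
        return T.transpose(T.reshape(h, (b2, n2, h2 * w2)), (0, 2, 1))


class DomainFusion(nn.Module):
    """Concatenate feature groups along the token axis, then mix channels
    with a kernel-1 convolution (sequence length preserved)."""

    def __init__(self, n, rng):
        super().__init__()
        self.conv = nn.Conv1d(n, n, 1, 1, rng)

    def __call__(self, parts):
        n = parts[0].shape[-1]
        if any(p.shape[-1] != n for p in parts):
            raise ValueError("all feature groups must share the embedding width")
        cat = T.concat(parts, axis=1)
        h = self.conv(T.transpose(cat, (0, 2, 1)))
        return T.transpose(h, (0, 2, 1))


class WeightedFusion(nn.Module):
    """MLP-gated fusion: each group is mean-pooled over tokens; a shared
    two-layer perceptron scores the pooled vectors and a softmax over the
    groups yields weights summing to one.

    mode "weighted": output is the weighted sum (one 1 x n token);
    mode "weighted_cnn": the weighted group vectors are kept as a length-3
    sequence and mixed by a kernel-1 convolution.
    """

    def __init__(self, n, rng, mode="weighted", hidden=16):
        super().__init__()
        if mode not in ("weighted", "weighted_cnn"):
            raise ValueError(f"unknown weighted-fusion mode {mode!r}")
        self.mode = mode
        self.score1 = nn.Linear(n, hidden, rng)
        self.score2 = nn.Linear(hidden, 1, rng)
        if mode == "weighted_cnn":
            self.conv = nn.Conv1d(n, n, 1, 1, rng)

    def weights(self, pooled):
        scores = [self.score2(T.elu(self.score1(p))) for p in pooled]  # each (B,1)
        return T.softmax(T.concat(scores, axis=-1), axis=-1)  # (B, groups)

    def __call__(self, parts):
        pooled = [T.mean(p, axis=1) for p in parts]            # each (B, n)
        w = self.weights(pooled)
        b, g = w.shape
        weighted = [T.mul(pooled[i], _slice_col(w, i)) for i in range(g)]
        if self.mode == "weighted":
            s = weighted[0]
            for v in weighted[1:]:
                s = T.add(s, v)
            return T.reshape(s, (b, 1, pooled[0].shape[-1]))
        stacked = T.concat([T.reshape(v, (b, 1, v.shape[-1])) for v in weighted], axis=1)
        h = self.conv(T.transpose(stacked, (0, 2, 1)))
        return T.transpose(h, (0, 2, 1))


def _slice_col(t, i):
    """Column i of a 2-D tensor, differentiably."""
    b, g = t.shape
    data = t.data[:, i : i + 1]

    def backward(grad):
        full = np.zeros_like(t.data)
        full[:, i : i + 1] = grad
        return (full,)

    return T._make(data, (t,), backward)


class Classifier(nn.Module):
    """Flatten -> FC(hidden) -> ELU -> Dropout -> FC(classes)."""

    def __init__(self, flat_width, hidden, num_classes, dropout, rng):
        super().__init__()
        self.flat_width = flat_width
        self.fc1 = nn.Linear(flat_width, hidden, rng)
        self.drop = nn.Dropout(dropout)
        self.fc2 = nn.Linear(hidden, num_classes, rng)

    def __call__(self, seq):
        b = seq.shape[0]
        flat = T.reshape(seq, (b, -1))
        if flat.shape[1] != self.flat_width:
            raise ValueError(f"flattened width {flat.shape[1]} does not match classifier input {self.flat_width}")
        h = self.drop(T.elu(self.fc1(flat)))
        return self.fc2(h)


@dataclass
class ClassProbs:
    """Logits z and softmax probabilities p for a batch."""

    z: np.ndarray
    p: np.ndarray


# ---------------------------------------------------------------------
# the full network
# ---------------------------------------------------------------------

class LGNet(nn.Module):
    """Local/global time + time-frequency fusion network (all variants)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.plan = shape_plan(cfg)
        rng = np.random.default_rng(cfg.seed)
        n = cfg.embed_dim
        tc = cfg.transformer

        self.time_conv = TimeConvStack(n, rng)
        if cfg.variant != "cnn":
            self.td_transformer = nn.TransformerEncoder(
                tc.num_layers, tc.d_model, tc.num_heads, tc.ffn_width, rng,
                positional_encoding=tc.positional_encoding,
            )
        if cfg.variant in ("cnn_tf_cnn_fusion", "full"):
            self.td_deep = DeepConv1d(n, rng)
            if cfg.fusion_strategy == "concat_cnn":
                self.td_fusion = DomainFusion(n, rng)
            else:
                self.td_fusion = WeightedFusion(n, rng, mode=cfg.fusion_strategy)
        if cfg.variant == "full":
            pad = self.plan["pad_time"]
            self.tf_conv = SpecConvStack(n, rng, pad_time=pad, table_order=cfg.table_kernel_order)
            self.tfd_transformer = nn.TransformerEncoder(
                tc.num_layers, tc.d_model, tc.num_heads, tc.ffn_width, rng,
                positional_encoding=tc.positional_encoding,
            )
            self.tf_deep = DeepConv2d(n, rng, pad_time=pad)
            if cfg.fusion_strategy == "concat_cnn":
                self.tfd_fusion = DomainFusion(n, rng)
            else:
                self.tfd_fusion = WeightedFusion(n, rng, mode=cfg.fusion_strategy)
        self.classifier = Classifier(
            self.plan["flat_width"], cfg.classifier_hidden, cfg.num_classes, cfg.dropout, rng
        )

    # -- helpers ------------------------------------------------------
    def seed_dropout(self, seed: int):
        for m in [self] + list(self.modules()):
            if isinstance(m, nn.Dropout):
                m.rng = np.random.default_rng(seed)

    def compute_spectrograms(self, x: np.ndarray) -> np.ndarray:
        """(B, L) waveforms -> (B, 1, bins, frames) log-magnitude STFTs."""
        specs = [
            stft_spectrogram(row, self.cfg.stft_window, self.cfg.stft_overlap,
                             log_scale=self.cfg.stft_log, fs=self.cfg.fs).values
            for row in np.asarray(x)
        ]
        return np.stack(specs)[:, None, :, :].astype(np.float32)

    # -- forward ------------------------------------------------------
    def forward(self, x, spec=None):
        """Batch of segments (B, L) [+ optional precomputed spectrograms]
        -> logits Tensor of shape (B, num_classes)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.plan["L"]:
            raise ValueError(f"expected segments of {self.plan['L']} samples, got {x.shape[1]}")
        xt = nn.Tensor(x[:, None, :])

        fa = self.time_conv(xt)                      # (B, T, n)
        if self.cfg.variant == "cnn":
            feats = fa
        else:
            ftr = self.td_transformer(fa)
            if self.cfg.variant == "cnn_tf":
                feats = ftr
            elif self.cfg.variant == "cnn_tf_fusion":
                feats = T.concat([fa, ftr], axis=1)
            else:
                fb = self.td_deep(ftr)
                f_td = self.td_fusion([fa, ftr, fb])
                if self.cfg.variant == "cnn_tf_cnn_fusion":
                    feats = f_td
                else:
                    if spec is None:
                        spec = self.compute_spectrograms(x)
                    st = nn.Tensor(np.asarray(spec, dtype=np.float32))
                    g = self.tf_conv(st)             # (B, n, H, W)
                    b, n, h, w = g.shape
                    fa2 = T.transpose(T.reshape(g, (b, n, h * w)), (0, 2, 1))
                    ftr2 = self.tfd_transformer(fa2)
                    fb2 = self.tf_deep(ftr2, h, w)
                    f_tfd = self.tfd_fusion([fa2, ftr2, fb2])
                    feats = T.concat([f_td, f_tfd], axis=1)   # time domain first
        return self.classifier(feats)

    __call__ = forward

    def predict_proba(self, x, spec=None, batch_size=16) -> ClassProbs:
        """Inference-mode class probabilities, computed in mini-batches."""
        was_training = self.training
        self.eval()
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        zs = []
        with T.no_grad():
            for i in range(0, x.shape[0], batch_size):
                sl = slice(i, i + batch_size)
                sp = None if spec is None else spec[sl]
                zs.append(self.forward(x[sl], sp).data)
        if was_training:
            self.train()
        z = np.concatenate(zs, axis=0)
        return ClassProbs(z=z, p=T.stable_softmax(z))

    def predict(self, x, spec=None, batch_size=16) -> np.ndarray:
        """Argmax class indices (ties broken toward the lowest index)."""
        return self.predict_proba(x, spec, batch_size).p.argmax(axis=1)


def build_model(cfg: ModelConfig) -> LGNet:
    """Construct the network for ``cfg`` (variant pruning included)."""
    return LGNet(cfg)


# ---------------------------------------------------------------------
# fusion as free functions (mirrors of the network's fusion stages)
# ---------------------------------------------------------------------

def fuse_total(f_td, f_tfd):
    """Concatenate domain feature sets along the token axis, time first."""
    if f_td.shape[-1] != f_tfd.shape[-1]:
        raise ValueError("embedding widths differ between domains")
    if f_td.shape[1] == 0 or f_tfd.shape[1] == 0:
        raise ValueError("cannot fuse an empty feature sequence")
    return T.concat([f_td, f_tfd], axis=1)


# ---------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------

def save_checkpoint(model: LGNet, path, class_vocabulary=None, extra=None):
    """Single-file archive: weights + full config + vocabulary + seed."""
    meta = {
        "config": model.cfg.to_dict(),
        "class_vocabulary": list(class_vocabulary or []),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(path):
    """Reconstruct an identical model (weights, config, vocabulary)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    cfg = ModelConfig.from_dict(meta["config"])
    model = LGNet(cfg)
    model.load_state_dict(state)
    return model, tuple(meta["class_vocabulary"]), meta["extra"]
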