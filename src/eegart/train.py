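"""Training protocol: Adam + cross-entropy, stratified 5-fold CV where each
fold's train:test split is 8:2, early stopping on a fold-internal
validation slice, and aggregate (mean +- SD) reporting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .metrics import EvalReport, evaluation_report
from .model import LGNet, ModelConfig, build_model
from .nn import Adam
from .nn import tensor as T

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 200
    max_epochs: int = 100
    early_stop_patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0
    deterministic: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("betas must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")

    def to_dict(self):
        return asdict(self)


def config_fingerprint(*cfgs) -> str:
    blob = json.dumps([c.to_dict() if hasattr(c, "to_dict") else c for c in cfgs],
                      sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Per-sample fold assignment for k-fold CV (disjoint, covering)."""

    fold_of: np.ndarray
    k: int

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_of == fold

    def train_mask(self, fold: int) -> np.ndarray:
        return self.fold_of != fold


def stratified_kfold(labels, k=5, seed=0) -> SplitPlan:
    """Seeded stratified partition; per-class counts across folds differ by
    at most one.  With k=5 each fold's train:test ratio is exactly 8:2."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    starved = classes[counts < k]
    if starved.size:
        raise ValueError(f"classes with fewer than k={k} samples: {starved.tolist()}")
    fold_of = np.empty(labels.size, dtype=np.int64)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        fold_of[test_idx] = fold
    return SplitPlan(fold_of, k)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

def cross_entropy(y_onehot, p) -> float:
    """-sum(y * log(p)) with p clamped to [1e-12, 1]; accepts batches."""
    y = np.asarray(y_onehot, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    losses = -(y * np.log(np.clip(p, 1e-12, 1.0))).sum(axis=-1)
    return float(losses.mean())


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

@dataclass
class TrainResult:
    model: LGNet
    history: pd.DataFrame
    best_epoch: int


def _forward_loss_acc(model, x, spec, y, batch_size):
    """Inference-mode mean loss and accuracy over a whole set."""
    losses, correct = [], 0
    model.eval()
    with T.no_grad():
        for i in range(0, x.shape[0], batch_size):
            sl = slice(i, min(i + batch_size, x.shape[0]))
            logits = model.forward(x[sl], None if spec is None else spec[sl])
            loss = T.softmax_cross_entropy(logits, y[sl])
            losses.append(loss.item() * (sl.stop - i))
            correct += int((logits.data.argmax(axis=1) == y[sl]).sum())
    model.train()
    return float(np.sum(losses) / x.shape[0]), correct / x.shape[0]


def train(model: LGNet, x, y, cfg: TrainConfig, spec=None, val_indices=None,
          log_every=0) -> TrainResult:
    """Minimise mean cross-entropy with Adam on (x, y).

    ``x`` is (N, L) float32; ``spec`` optional precomputed spectrograms.
    When ``val_indices`` is None a stratified ``val_fraction`` slice is
    held out for early stopping (patience ``early_stop_patience``); the
    best-validation-loss weights are restored before returning.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed if cfg.deterministic else None)
    model.seed_dropout(int(rng.integers(2**31)))

    if val_indices is None and cfg.val_fraction > 0 and cfg.early_stop_patience > 0:
        n_classes = np.unique(y).size
        val_n = max(int(round(cfg.val_fraction * y.size)), n_classes)
        if val_n >= y.size:
            train_idx, val_idx = np.arange(y.size), None
        else:
            sss = StratifiedShuffleSplit(n_splits=1, test_size=val_n,
                                         random_state=cfg.seed)
            train_idx, val_idx = next(sss.split(np.zeros(y.size), y))
    elif val_indices is not None:
        val_idx = np.asarray(val_indices)
        train_idx = np.setdiff1d(np.arange(y.size), val_idx)
    else:
        train_idx, val_idx = np.arange(y.size), None

    opt = Adam(model.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2)
    model.train()
    rows = []
    best_val, best_state, best_epoch, stall = np.inf, None, 0, 0
    for epoch in range(cfg.max_epochs):
        order = train_idx[rng.permutation(train_idx.size)]
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, order.size, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            logits = model.forward(x[idx], None if spec is None else spec[idx])
            loss = T.softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item() * idx.size
            ep_correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        train_loss = ep_loss / order.size
        train_acc = ep_correct / order.size
        if val_idx is not None and val_idx.size:
            val_loss, val_acc = _forward_loss_acc(
                model, x[val_idx], None if spec is None else spec[val_idx],
                y[val_idx], cfg.batch_size)
        else:
            val_loss, val_acc = np.nan, np.nan
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
                     "train_acc": train_acc, "val_acc": val_acc})
        if log_every and epoch % log_every == 0:
            logger.info("epoch %d: train_loss=%.4f train_acc=%.3f val_loss=%.4f val_acc=%.3f",
                        epoch, train_loss, train_acc, val_loss, val_acc)
        if val_idx is not None and val_idx.size:
            if val_loss < best_val - 1e-6:
                best_val, best_epoch, stall = val_loss, epoch, 0
                best_state = model.state_dict()
            else:
                stall += 1
                if stall >= cfg.early_stop_patience:
                    break
        else:
            best_epoch = epoch
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model, pd.DataFrame(rows), best_epoch)


def evaluate(model: LGNet, x, y, class_names, mask=None, spec=None,
             fold=None, fingerprint=None) -> EvalReport:
    """One-vs-rest metrics of argmax predictions on the masked samples."""
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if mask is not None:
        mask = np.asarray(mask)
        if not mask.any():
            raise ValueError("evaluation mask selects no samples")
        x, y = x[mask], y[mask]
        spec = None if spec is None else spec[mask]
    preds = model.predict(x, spec)
    return evaluation_report(y, preds, class_names, fold=fold, fingerprint=fingerprint)


# ---------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------

@dataclass
class CVResult:
    fold_reports: list
    mean: dict
    std: dict
    histories: list = field(default_factory=list)

    def to_dict(self):
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "mean": self.mean,
            "std": self.std,
        }


def run_cv(dataset, model_cfg: ModelConfig, train_cfg: TrainConfig, k=5,
           log_every=0) -> CVResult:
    """Train one model per fold and aggregate macro metrics (mean +- SD)."""
    x = dataset.signal_matrix()
    y = dataset.encoded_labels()
    names = list(dataset.class_vocabulary)
    if model_cfg.num_classes != len(names):
        raise ValueError(f"model num_classes={model_cfg.num_classes} but dataset has {len(names)} classes")
    fp = config_fingerprint(model_cfg, train_cfg)
    plan = stratified_kfold(y, k=k, seed=train_cfg.seed)

    probe = build_model(model_cfg)
    spec = probe.compute_spectrograms(x) if model_cfg.variant == "full" else None

    reports, histories = [], []
    for fold in range(k):
        cfg_f = ModelConfig.from_dict({**model_cfg.to_dict(), "seed": model_cfg.seed + 1000 * fold})
        tcfg_f = TrainConfig(**{**train_cfg.to_dict(), "seed": train_cfg.seed + 1000 * fold})
        model = build_model(cfg_f)
        tr = plan.train_mask(fold).nonzero()[0]
        result = train(model, x[tr], y[tr], tcfg_f,
                       spec=None if spec is None else spec[tr], log_every=log_every)
        rep = evaluate(result.model, x, y, names, mask=plan.test_mask(fold),
                       spec=spec, fold=fold, fingerprint=fp)
        logger.info("fold %d: overall_acc=%.3f macro_f1=%.3f (best epoch %d)",
                    fold, rep.overall_accuracy, rep.macro["f1"], result.best_epoch)
        reports.append(rep)
        histories.append(result.history)

    keys = ("accuracy", "recall", "f1")
    mean = {key: float(np.mean([r.macro[key] for r in reports])) for key in keys}
    std = {key: float(np.std([r.macro[key] for r in reports])) for key in keys}
    mean["overall_accuracy"] = float(np.mean([r.overall_accuracy for r in reports]))
    std["overall_accuracy"] = float(np.std([r.overall_accuracy for r in reports]))
    return CVResult(reports, mean, std, histories)
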