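"""Evaluation metrics: one-vs-rest confusion counts, accuracy, recall, F1.

Per-class metrics treat that class as positive and every other class as
negative, derived from the multi-class confusion matrix of argmax
predictions; "macro" averages are unweighted means across classes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def accuracy(self) -> float:
        return _safe_div(self.tp + self.tn, self.total, "accuracy")

    def recall(self) -> float:
        return _safe_div(self.tp, self.tp + self.fn, "recall")

    def f1(self) -> float:
        return _safe_div(2 * self.tp, 2 * self.tp + self.fp + self.fn, "f1")


def _safe_div(num, den, name):
    if den == 0:
        logger.warning("zero denominator for %s; reporting 0", name)
        return 0.0
    return num / den


def one_vs_rest_counts(y_true, y_pred, num_classes) -> list[ConfusionCounts]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    out = []
    for c in range(num_classes):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        tn = int(np.sum((y_true != c) & (y_pred != c)))
        out.append(ConfusionCounts(tp, tn, fp, fn))
    return out


@dataclass
class EvalReport:
    """Per-class and macro-averaged accuracy/recall/F1 with provenance."""

    per_class: dict            # class name -> {"accuracy","recall","f1"}
    macro: dict                # same keys, unweighted means
    n_samples: int
    overall_accuracy: float    # plain multi-class accuracy (argmax == label)
    fold: int | None = None
    config_fingerprint: str | None = None
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def evaluation_report(y_true, y_pred, class_names, fold=None, fingerprint=None) -> EvalReport:
    counts = one_vs_rest_counts(y_true, y_pred, len(class_names))
    per_class, raw = {}, {}
    for name, c in zip(class_names, counts):
        per_class[name] = {"accuracy": c.accuracy(), "recall": c.recall(), "f1": c.f1()}
        raw[name] = {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
    macro = {
        key: float(np.mean([per_class[name][key] for name in class_names]))
        for key in ("accuracy", "recall", "f1")
    }
    overall = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    return EvalReport(per_class, macro, int(np.asarray(y_true).size), overall,
                      fold=fold, config_fingerprint=fingerprint, counts=raw)
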