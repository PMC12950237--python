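"""Training harness and metrics: fold arithmetic, loss values, metric
identities against brute force and scikit-learn, and a small end-to-end
learning check on trivially separable tones."""

import numpy as np
import pytest

from eegart.metrics import ConfusionCounts, evaluation_report, one_vs_rest_counts
from eegart.model import ModelConfig, build_model
from eegart.train import (
    TrainConfig,
    config_fingerprint,
    cross_entropy,
    evaluate,
    stratified_kfold,
    train,
)


class TestStratifiedKFold:
    def test_eight_to_two_ratio_with_balanced_classes(self):
        labels = np.repeat(np.arange(6), 400)   # 2400 samples
        plan = stratified_kfold(labels, k=5, seed=0)
        for fold in range(5):
            test = plan.test_mask(fold)
            assert test.sum() == 480
            assert plan.train_mask(fold).sum() == 1920
            # exact stratification: 80 per class in every fold's test set
            per_class = np.bincount(labels[test], minlength=6)
            np.testing.assert_array_equal(per_class, 80)

    def test_folds_disjoint_and_covering(self):
        labels = np.repeat(np.arange(3), 25)
        plan = stratified_kfold(labels, k=5, seed=1)
        seen = np.zeros(labels.size, dtype=int)
        for fold in range(5):
            seen += plan.test_mask(fold).astype(int)
        np.testing.assert_array_equal(seen, 1)

    def test_deterministic_given_seed(self):
        labels = np.repeat(np.arange(4), 10)
        a = stratified_kfold(labels, k=5, seed=3).fold_of
        b = stratified_kfold(labels, k=5, seed=3).fold_of
        c = stratified_kfold(labels, k=5, seed=4).fold_of
        np.testing.assert_array_equal(a, b)
        assert np.any(a != c)

    def test_starved_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array([0, 0, 0, 1, 1, 1, 1, 1]), k=5)


class TestCrossEntropy:
    def test_closed_form_values(self):
        assert cross_entropy([0, 1, 0], [0.0, 1.0, 0.0]) == pytest.approx(0.0)
        assert cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-9)

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(20):
            k = rng.integers(2, 6)
            y = np.eye(k)[rng.integers(0, k)]
            p = rng.dirichlet(np.ones(k))
            assert cross_entropy(y, p) >= 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy([0, 1], [0.2, 0.3, 0.5])


class TestMetrics:
    def test_hand_specified_counts(self):
        """TP=8, FN=2, FP=1, TN=9 -> accuracy 0.85, recall 0.8, F1 16/19."""
        c = ConfusionCounts(tp=8, tn=9, fp=1, fn=2)
        assert c.accuracy() == pytest.approx(0.85)
        assert c.recall() == pytest.approx(0.8)
        assert c.f1() == pytest.approx(16 / 19)

    def test_perfect_predictions_all_ones(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = evaluation_report(y, y, ["a", "b", "c"])
        for cls in rep.per_class.values():
            assert cls == {"accuracy": 1.0, "recall": 1.0, "f1": 1.0}
        assert rep.overall_accuracy == 1.0

    def test_brute_force_equivalence_on_random_pairs(self, rng):
        """Counts-based metrics equal metrics recomputed from raw
        (label, prediction) pairs, and agree with scikit-learn."""
        from sklearn.metrics import f1_score, recall_score

        y = rng.integers(0, 4, size=200)
        p = rng.integers(0, 4, size=200)
        counts = one_vs_rest_counts(y, p, 4)
        for c in range(4):
            tp = sum(1 for a, b in zip(y, p) if a == c and b == c)
            fn = sum(1 for a, b in zip(y, p) if a == c and b != c)
            fp = sum(1 for a, b in zip(y, p) if a != c and b == c)
            tn = 200 - tp - fn - fp
            assert (counts[c].tp, counts[c].fn, counts[c].fp, counts[c].tn) == (tp, fn, fp, tn)
        rep = evaluation_report(y, p, list("abcd"))
        skl_rec = recall_score(y, p, average=None, zero_division=0)
        skl_f1 = f1_score(y, p, average=None, zero_division=0)
        for i, name in enumerate("abcd"):
            assert rep.per_class[name]["recall"] == pytest.approx(skl_rec[i])
            assert rep.per_class[name]["f1"] == pytest.approx(skl_f1[i])

    def test_f1_is_harmonic_mean_where_defined(self, rng):
        y = rng.integers(0, 3, size=120)
        p = rng.integers(0, 3, size=120)
        for c in one_vs_rest_counts(y, p, 3):
            if c.tp + c.fp and c.tp + c.fn and c.tp:
                prec = c.tp / (c.tp + c.fp)
                rec = c.recall()
                assert c.f1() == pytest.approx(2 * prec * rec / (prec + rec))

    def test_zero_denominator_reports_zero_with_warning(self, caplog):
        rep = evaluation_report([0, 0], [0, 0], ["a", "b"])
        assert rep.per_class["b"]["recall"] == 0.0

    def test_counts_sum_to_total(self, rng):
        y = rng.integers(0, 5, size=77)
        p = rng.integers(0, 5, size=77)
        for c in one_vs_rest_counts(y, p, 5):
            assert c.total == 77


def _tone_dataset(n_per_class=50, seconds=4.0, fs=250.0, seed=0):
    """Two trivially separable classes: 5 Hz vs 40 Hz tones in noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(seconds * fs)) / fs
    xs, ys = [], []
    for label, freq in enumerate((5.0, 40.0)):
        for _ in range(n_per_class):
            phase = rng.uniform(0, 2 * np.pi)
            x = np.sin(2 * np.pi * freq * t + phase) + 0.3 * rng.standard_normal(t.size)
            xs.append((x - x.mean()) / x.std())
            ys.append(label)
    return np.asarray(xs, dtype=np.float32), np.asarray(ys)


class TestTraining:
    def test_separable_tones_reach_full_training_accuracy(self):
        """5 Hz vs 40 Hz tones are separable in band power; the conv
        variant fits them to 100% training accuracy within 20 epochs."""
        x, y = _tone_dataset()
        cfg = ModelConfig(variant="cnn", num_classes=2, seed=0)
        model = build_model(cfg)
        tcfg = TrainConfig(batch_size=20, max_epochs=20, early_stop_patience=0,
                           val_fraction=0.0, seed=0)
        result = train(model, x, y, tcfg)
        assert result.history["train_acc"].iloc[-1] == 1.0
        assert np.isfinite(result.history["train_loss"]).all()

    def test_identical_seeds_reproduce_identical_history(self):
        x, y = _tone_dataset(n_per_class=10)
        histories = []
        for _ in range(2):
            model = build_model(ModelConfig(variant="cnn", num_classes=2, seed=1))
            tcfg = TrainConfig(batch_size=10, max_epochs=2, val_fraction=0.0,
                               early_stop_patience=0, seed=1)
            histories.append(train(model, x, y, tcfg).history)
        assert histories[0].equals(histories[1])

    def test_empty_dataset_rejected(self):
        model = build_model(ModelConfig(variant="cnn", num_classes=2))
        with pytest.raises(ValueError):
            train(model, np.empty((0, 1000)), np.empty(0, dtype=int), TrainConfig())

    def test_evaluate_requires_nonempty_mask(self):
        x, y = _tone_dataset(n_per_class=3)
        model = build_model(ModelConfig(variant="cnn", num_classes=2))
        with pytest.raises(ValueError):
            evaluate(model, x, y, ["lo", "hi"], mask=np.zeros(6, dtype=bool))

    def test_invalid_train_config(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(beta1=1.5)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


def test_lower_snr_reduces_accuracy():
    """Burying the artifacts in background noise (snr -10 dB vs +10 dB)
    lowers mean test accuracy of the conv variant, averaged over 3 seeds."""
    from eegart.synth import generate_dataset
    from eegart.train import run_cv

    def mean_acc(snr_db):
        accs = []
        for seed in range(3):
            ds = generate_dataset({"MUSC": 10, "EYEM": 10, "SHIV": 10},
                                  duration_s=2.0, fs=250.0, snr_db=snr_db, seed=seed)
            for s in ds.segments:
                s.x = (s.x - s.x.mean()) / max(s.x.std(), 1e-8)
            cfg = ModelConfig(variant="cnn", num_classes=3, segment_seconds=2.0, seed=seed)
            tcfg = TrainConfig(batch_size=6, max_epochs=8, val_fraction=0.0,
                               early_stop_patience=0, seed=seed)
            accs.append(run_cv(ds, cfg, tcfg, k=5).mean["overall_accuracy"])
        return np.mean(accs)

    assert mean_acc(10.0) > mean_acc(-10.0)


def test_fingerprint_stable_and_sensitive():
    a = config_fingerprint(ModelConfig(num_classes=6), TrainConfig())
    b = config_fingerprint(ModelConfig(num_classes=6), TrainConfig())
    c = config_fingerprint(ModelConfig(num_classes=7), TrainConfig())
    assert a == b != c
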