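"""Train the light-weight conv variant on two separable tone classes and
report one-vs-rest metrics.

A 5 Hz and a 40 Hz tone class differ in band power, so the convolutional
branch alone separates them within a few epochs; this demonstrates the
training loop, early stopping and the evaluation report end to end in
about a minute.  The full dual-branch model trains the same way (see
scripts/acceptance.py for the cross-validated run).
"""

import numpy as np

from eegart import ModelConfig, TrainConfig, build_model, evaluate, train

rng = np.random.default_rng(0)
fs, seconds, n_per_class = 250.0, 4.0, 40
t = np.arange(int(seconds * fs)) / fs
xs, ys = [], []
for label, freq in enumerate((5.0, 40.0)):
    for _ in range(n_per_class):
        x = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        x = x + 0.5 * rng.standard_normal(t.size)
        xs.append((x - x.mean()) / x.std())
        ys.append(label)
x = np.asarray(xs, dtype=np.float32)
y = np.asarray(ys)

model = build_model(ModelConfig(variant="cnn", num_classes=2, seed=0))
result = train(model, x, y, TrainConfig(batch_size=16, max_epochs=15, seed=0))
print(result.history[["epoch", "train_loss", "train_acc", "val_acc"]].to_string(index=False))

report = evaluate(result.model, x, y, ["tone5Hz", "tone40Hz"])
print(f"\noverall accuracy: {report.overall_accuracy:.3f}")
for name, m in report.per_class.items():
    print(f"  {name}: accuracy {m['accuracy']:.3f}  recall {m['recall']:.3f}  F1 {m['f1']:.3f}")
print("\nTraining accuracy reaching 1.0 confirms the optimisation loop;")
print("per-class metrics are one-vs-rest from the confusion matrix.")
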