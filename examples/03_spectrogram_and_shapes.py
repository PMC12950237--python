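"""Trace one 4 s segment through both branches and print every shape.

Shows the exact sequence-length law of the reference configuration:
T=59 time-branch tokens, 126x16 spectrogram, 122x12 feature map (1464
tokens), deep features T1=57 / T2=1200, fused lengths 175 + 4128 = 4303.
"""

import numpy as np

from eegart import ModelConfig, build_model, generate_artifact_segment, stft_spectrogram
from eegart.synth import SynthParams
from eegart import nn
from eegart.nn import tensor as T

seg = generate_artifact_segment(SynthParams("RC", duration_s=4.0, fs=250.0, seed=1))
x = ((seg.x - seg.x.mean()) / seg.x.std()).astype(np.float32)[None, :]

model = build_model(ModelConfig(num_classes=6, seed=0)).eval()
spec = stft_spectrogram(seg)
print(f"segment: {x.shape[1]} samples -> spectrogram {spec.values.shape}")

with T.no_grad():
    fa = model.time_conv(nn.Tensor(x[:, None, :]))
    ftr = model.td_transformer(fa)
    fb = model.td_deep(ftr)
    f_td = model.td_fusion([fa, ftr, fb])
    print(f"time branch:   shallow {fa.shape} -> global {ftr.shape} -> deep {fb.shape}")
    print(f"               fused   {f_td.shape}   (2*59 + 57 = 175 tokens)")

    g = model.tf_conv(nn.Tensor(model.compute_spectrograms(x)))
    fa2 = T.transpose(T.reshape(g, (1, 40, g.shape[2] * g.shape[3])), (0, 2, 1))
    ftr2 = model.tfd_transformer(fa2)
    fb2 = model.tf_deep(ftr2, g.shape[2], g.shape[3])
    f_tfd = model.tfd_fusion([fa2, ftr2, fb2])
    print(f"t-f branch:    feature map {g.shape} -> {fa2.shape[1]} tokens")
    print(f"               deep {fb2.shape} -> fused {f_tfd.shape} (2*1464 + 1200 = 4128)")

probs = model.predict_proba(x)
print(f"\ntotal fused length: {f_td.shape[1] + f_tfd.shape[1]} tokens x 40 dims")
print(f"class probabilities (untrained, ~uniform): {np.round(probs.p[0], 3)}")
print(f"trainable parameters: {model.num_parameters():,}")
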