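"""Condition a raw EDF recording into labeled 4 s training segments.

Builds a synthetic two-channel 256 Hz EDF plus an annotation CSV, then runs
the full pipeline: polyphase resampling to 250 Hz, 0.5-80 Hz band-pass,
50 Hz notch, annotation-driven extraction and non-overlapping windowing.
"""

import tempfile
from pathlib import Path

import numpy as np

from eegart import PreprocessConfig, RawRecording, preprocess_recording
from eegart import io as eio
from eegart.preprocess import AnnotationInterval

tmp = Path(tempfile.mkdtemp())
fs_in = 256.0
rng = np.random.default_rng(0)
rec = RawRecording(40 * rng.standard_normal((2, int(30 * fs_in))), fs_in,
                   ["FP1-F7", "FP2-F8"])
eio.write_edf(tmp / "demo.edf", rec)
eio.write_annotations(tmp / "demo.csv", [
    AnnotationInterval("FP1-F7", 2.0, 15.0, "CHEW"),   # 13 s -> 3 windows
    AnnotationInterval("FP2-F8", 5.0, 11.5, "MUSC"),   # 6.5 s -> 1 window
    AnnotationInterval("FP2-F8", 20.0, 22.0, "EYEM"),  # too short, dropped
])

recording = eio.read_edf(tmp / "demo.edf")
annotations = eio.read_annotations(tmp / "demo.csv")
segments = preprocess_recording(recording, annotations,
                                PreprocessConfig(segment_seconds=4.0, min_seconds=4.0))

print(f"input: {recording.samples.shape[1]} samples/channel at {recording.fs:g} Hz")
print(f"extracted {len(segments)} segments:")
for s in segments:
    print(f"  {s.label:5s} from {s.source['channel']:7s} "
          f"window {s.source['window_index']}: {len(s)} samples at {s.fs:g} Hz")
print("\n13 s and 6.5 s annotations yield 3 + 1 non-overlapping 4 s windows;")
print("the 2 s interval is below the 4 s minimum and is dropped.")
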