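"""Core container: one fixed-length, single-channel labeled EEG segment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGSegment:
    """A single-channel waveform x(n) with its sampling rate and label.

    ``x`` is a 1-D float array (nominal microvolts unless standardized),
    ``label`` an artifact class name or ``None`` for unlabeled data, and
    ``source`` free-form provenance (recording, channel, onset, ...).
    """

    x: np.ndarray
    fs: float
    label: str | None = None
    source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("segment contains non-finite samples")

    def __len__(self):
        return self.x.size

    @property
    def duration_s(self) -> float:
        return self.x.size / self.fs
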