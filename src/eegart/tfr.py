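"""Time-frequency representation: the STFT spectrogram fed to the 2-D branch.

The canonical configuration is a Hamming window of 250 samples (1 s at
250 Hz) with 200 samples overlap (hop 50), one-sided magnitude, and
log(1 + m) compression.  No boundary padding or centering is applied, so a
4 s segment at 250 Hz yields exactly (250/2 + 1) x 16 = 126 x 16 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .segment import EEGSegment


@dataclass
class Spectrogram:
    """Magnitude (or log-magnitude) STFT: frequency bins x time frames."""

    values: np.ndarray
    freq_axis: np.ndarray   # Hz per bin, 0 .. fs/2
    time_axis: np.ndarray   # seconds at each frame center
    window_len: int
    overlap: int

    @property
    def shape(self):
        return self.values.shape


def stft_spectrogram(segment, window_len=250, overlap=200, log_scale=True, fs=None):
    """One-sided Hamming-windowed magnitude STFT of a 1-D segment.

    hop = window_len - overlap; frames = (L - window_len)//hop + 1.
    With ``log_scale`` values become log1p(magnitude).
    """
    if isinstance(segment, EEGSegment):
        x, fs = segment.x, segment.fs
    else:
        x = np.asarray(segment, dtype=np.float64).ravel()
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    if overlap >= window_len:
        raise ValueError(f"overlap ({overlap}) must be smaller than window_len ({window_len})")
    if x.size < window_len:
        raise ValueError(f"segment length {x.size} shorter than window {window_len}")
    hop = window_len - overlap
    n_frames = (x.size - window_len) // hop + 1
    win = get_window("hamming", window_len, fftbins=True)
    frames = np.lib.stride_tricks.sliding_window_view(x, window_len)[::hop][:n_frames]
    mag = np.abs(np.fft.rfft(frames * win, axis=1)).T  # bins x frames
    if log_scale:
        mag = np.log1p(mag)
    freq_axis = np.fft.rfftfreq(window_len, d=1.0 / fs)
    centers = (np.arange(n_frames) * hop + window_len / 2.0) / fs
    return Spectrogram(mag, freq_axis, centers, window_len, overlap)
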