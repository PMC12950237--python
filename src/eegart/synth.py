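"""Synthetic EEG artifact generator.

Produces labeled single-channel segments whose class-conditional temporal
and spectral morphology mimics the artifact taxonomy used in EEG artifact
corpora (eye movement, blink trains, chewing EMG bursts, rhythmic chewing,
sustained muscle noise, electrode faults, shivering) superimposed on a 1/f
"pink" background with an alpha-band component.  The waveforms are signal
phenomenology, not forward-modeled physiology: they give each class a
distinct, learnable temporal/spectral signature at a controlled SNR so the
preprocessing, training and evaluation stages can be exercised end to end
without external recordings.

Class signatures
----------------
EYEM   slow 0.5-2 Hz half-sine deflections (ocular dipole rotation)
BLINK  stereotyped biphasic 200-400 ms transients repeating at 1-3 Hz
CHEW   20-60 Hz band-limited EMG bursts with jittered (irregular) onsets
RC     the same EMG bursts with strictly periodic onsets ("rhythmic chewing")
MUSC   sustained broadband 20-80 Hz muscle noise
ELEC   electrode faults: baseline step, impulsive pops, or flat-line dropout
SHIV   ~10 Hz sinusoidal bursts (shivering tremor)

All generation is deterministic given the seed; per-segment seeds are
derived from (master seed, class, index) so any subset of a dataset is
reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .segment import EEGSegment

ARTIFACT_CLASSES = ("CHEW", "MUSC", "ELEC", "EYEM", "SHIV", "RC", "BLINK")
CLASS_VOCABULARY = ARTIFACT_CLASSES + ("BACKGROUND",)

#: nominal peak amplitudes in microvolts (plausible clinical scales)
DEFAULT_AMPLITUDE_UV = {
    "EYEM": 150.0, "BLINK": 150.0,
    "CHEW": 80.0, "RC": 80.0, "MUSC": 80.0,
    "ELEC": 300.0, "SHIV": 60.0, "BACKGROUND": 0.0,
}

#: default event/burst repetition rates in Hz
DEFAULT_RATE_HZ = {
    "EYEM": 0.75, "BLINK": 2.0, "CHEW": 1.5, "RC": 2.0,
    "SHIV": 1.0, "MUSC": 0.0, "ELEC": 0.0, "BACKGROUND": 0.0,
}

BACKGROUND_RMS_UV = 15.0


@dataclass
class SynthParams:
    """Everything that determines one synthetic segment (bit-reproducibly)."""

    class_label: str
    duration_s: float = 4.0
    fs: float = 250.0
    snr_db: float | None = 10.0
    rate_hz: float | None = None
    amplitude_uv: float | None = None
    alpha_power: float = 0.3
    seed: int = 0

    def __post_init__(self):
        label = self.class_label.upper()
        if label not in CLASS_VOCABULARY:
            raise ValueError(f"unknown class label {self.class_label!r}; expected one of {CLASS_VOCABULARY}")
        self.class_label = label
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rate_hz is None:
            self.rate_hz = DEFAULT_RATE_HZ[label]
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be nonnegative")
        if self.amplitude_uv is None:
            self.amplitude_uv = DEFAULT_AMPLITUDE_UV[label]


@dataclass
class LabeledDataset:
    """Ordered segments + labels + the vocabulary fixing integer encoding."""

    segments: list
    labels: list
    class_vocabulary: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.segments) != len(self.labels):
            raise ValueError("segments and labels differ in length")
        unknown = set(self.labels) - set(self.class_vocabulary)
        if unknown:
            raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")

    def __len__(self):
        return len(self.segments)

    @property
    def fs(self) -> float:
        return self.segments[0].fs

    def signal_matrix(self) -> np.ndarray:
        """(n_segments, n_samples) float32 matrix of the waveforms."""
        return np.stack([s.x for s in self.segments]).astype(np.float32)

    def encoded_labels(self) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.class_vocabulary)}
        return np.asarray([index[l] for l in self.labels], dtype=np.int64)

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            [self.segments[i] for i in idx],
            [self.labels[i] for i in idx],
            self.class_vocabulary,
            dict(self.meta),
        )


# ---------------------------------------------------------------------
# background
# ---------------------------------------------------------------------

def background_eeg(duration_s, fs, alpha_power=0.3, seed=0, rng=None):
    """1/f (pink) background plus an 8-12 Hz alpha component.

    ``alpha_power`` is the fraction of total power contributed by the
    alpha band; the result is standardized to zero mean, unit variance.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    if n < 1:
        raise ValueError("duration_s * fs must be at least one sample")
    if not 0.0 <= alpha_power <= 1.0:
        raise ValueError("alpha_power must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)

    # pink noise: shape white Gaussian spectrum by 1/sqrt(f)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    pink = np.fft.irfft(spec * shaping, n=n)
    pink /= max(pink.std(), 1e-12)

    x = np.sqrt(max(1.0 - alpha_power, 0.0)) * pink
    if alpha_power > 0 and n > 16:
        sos = sps.butter(4, [8.0, 12.0], btype="bandpass", fs=fs, output="sos")
        alpha = sps.sosfilt(sos, rng.standard_normal(n))
        alpha /= max(alpha.std(), 1e-12)
        x = x + np.sqrt(alpha_power) * alpha

    x -= x.mean()
    x /= max(x.std(), 1e-12)
    return EEGSegment(x, fs, label="BACKGROUND", source={"seed": seed, "alpha_power": alpha_power})


# ---------------------------------------------------------------------
# class-specific artifact waveforms (unit-free; scaled afterwards)
# ---------------------------------------------------------------------

def _emg_noise(rng, n, fs, lo, hi):
    band_hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, band_hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x / max(x.std(), 1e-12)


def _burst_train(rng, n, fs, rate_hz, burst_s, jitter_frac, carrier):
    """Place ``carrier``-filled bursts at onsets spaced 1/rate with
    uniform +-jitter_frac * interval jitter (0 => strictly periodic)."""
    out = np.zeros(n)
    if rate_hz <= 0:
        return out
    interval = fs / rate_hz
    burst_n = max(int(round(burst_s * fs)), 4)
    env = np.hanning(burst_n)
    onset = rng.uniform(0, interval * 0.5)
    while onset < n:
        i0 = int(round(onset))
        i1 = min(i0 + burst_n, n)
        if i1 > i0:
            out[i0:i1] += carrier(i1 - i0) * env[: i1 - i0]
        jitter = rng.uniform(-jitter_frac, jitter_frac) * interval if jitter_frac > 0 else 0.0
        onset += interval + jitter
    return out


def _eyem(rng, n, fs, rate_hz):
    """Slow half-sine deflections of alternating polarity, 0.5-2 Hz."""
    out = np.zeros(n)
    interval = fs / max(rate_hz, 1e-6)
    pos = rng.uniform(0, 0.5 * interval)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    while pos < n:
        dur = rng.uniform(0.5, 1.0)  # seconds per deflection
        m = int(dur * fs)
        i0, i1 = int(pos), min(int(pos) + m, n)
        if i1 > i0:
            out[i0:i1] += sign * np.sin(np.pi * np.arange(i1 - i0) / m)
        sign = -sign
        pos += interval + rng.uniform(-0.15, 0.15) * interval
    return out


def _blink_waveform(fs, dur_s):
    """Stereotyped biphasic transient: dominant positive lobe followed by a
    smaller negative rebound (classic frontal blink shape)."""
    m = int(dur_s * fs)
    t = np.linspace(0, 1, m, endpoint=False)
    main = np.sin(np.pi * np.clip(t / 0.7, 0, 1)) ** 2
    rebound = -0.35 * np.sin(np.pi * np.clip((t - 0.65) / 0.35, 0, 1))
    return main + rebound


def _blink(rng, n, fs, rate_hz):
    out = np.zeros(n)
    dur = rng.uniform(0.2, 0.4)          # one stereotyped shape per segment
    wave = _blink_waveform(fs, dur)
    interval = fs / max(rate_hz, 1e-6)
    pos = rng.uniform(0, 0.5 * interval)
    while pos < n:
        i0 = int(pos)
        i1 = min(i0 + wave.size, n)
        out[i0:i1] += wave[: i1 - i0]
        pos += interval + rng.uniform(-0.05, 0.05) * interval
    return out


def _elec(rng, n, fs, background):
    """Electrode fault; returns (artifact, replace_mask) where samples under
    the mask overwrite the mixed signal (flat-line dropout)."""
    out = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    subtype = rng.choice(["step", "pop", "dropout"])
    if subtype == "step":
        at = rng.integers(n // 8, 7 * n // 8)
        out[at:] = rng.choice([-1.0, 1.0])
        # slow exponential return toward baseline
        out[at:] *= np.exp(-np.arange(n - at) / (2.0 * fs))
    elif subtype == "pop":
        for _ in range(rng.integers(1, 5)):
            at = rng.integers(0, n - int(0.05 * fs) - 1)
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.0)
            decay = np.exp(-np.arange(int(0.05 * fs)) / (0.008 * fs))
            out[at : at + decay.size] += amp * decay
    else:  # dropout: electrode disconnect, signal collapses to near-zero
        i0 = rng.integers(0, n // 2)
        i1 = rng.integers(i0 + n // 4, n)
        mask[i0:i1] = True
        out[i0:i1] = 0.02 * rng.standard_normal(i1 - i0)
    return out, mask, subtype


def generate_artifact_segment(params: SynthParams) -> EEGSegment:
    """One labeled synthetic segment: class-specific artifact over 1/f
    background, mixed at ``snr_db`` (artifact power / background power)."""
    p = params
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration_s * p.fs))
    bg = background_eeg(p.duration_s, p.fs, p.alpha_power, rng=rng).x * BACKGROUND_RMS_UV

    label = p.class_label
    replace_mask = None
    subtype = None
    if label == "BACKGROUND":
        art = np.zeros(n)
    elif label == "EYEM":
        art = _eyem(rng, n, p.fs, p.rate_hz)
    elif label == "BLINK":
        art = _blink(rng, n, p.fs, p.rate_hz)
    elif label == "CHEW":
        art = _burst_train(rng, n, p.fs, p.rate_hz, burst_s=0.25, jitter_frac=0.3,
                           carrier=lambda m: _emg_noise(rng, m, p.fs, 20.0, 60.0))
    elif label == "RC":
        art = _burst_train(rng, n, p.fs, p.rate_hz, burst_s=0.25, jitter_frac=0.0,
                           carrier=lambda m: _emg_noise(rng, m, p.fs, 20.0, 60.0))
    elif label == "MUSC":
        art = _emg_noise(rng, n, p.fs, 20.0, 80.0)
    elif label == "SHIV":
        tremor_hz = rng.uniform(9.0, 11.0)
        t = np.arange(n) / p.fs
        art = _burst_train(rng, n, p.fs, p.rate_hz, burst_s=0.5, jitter_frac=0.1,
                           carrier=lambda m: np.ones(m))
        art = art * np.sin(2 * np.pi * tremor_hz * t + rng.uniform(0, 2 * np.pi))
    elif label == "ELEC":
        art, replace_mask, subtype = _elec(rng, n, p.fs, bg)
    else:  # pragma: no cover - guarded by SynthParams
        raise ValueError(f"unknown class label {label!r}")

    if label != "BACKGROUND":
        art = art * p.amplitude_uv
        if p.snr_db is not None and art.std() > 0:
            target_power = np.mean(bg**2) * 10.0 ** (p.snr_db / 10.0)
            art = art * np.sqrt(target_power / max(np.mean(art**2), 1e-12))

    x = bg + art
    if replace_mask is not None and replace_mask.any():
        x[replace_mask] = art[replace_mask]

    source = {"generator": "synth", "seed": p.seed, "snr_db": p.snr_db, "rate_hz": p.rate_hz}
    if subtype:
        source["elec_subtype"] = subtype
    return EEGSegment(x, p.fs, label=label, source=source)


def _segment_seed(master_seed: int, class_label: str, index: int) -> int:
    """Stable per-segment seed from (master seed, class, index)."""
    ss = np.random.SeedSequence([int(master_seed), ARTIFACT_CLASSES.index(class_label)
                                 if class_label in ARTIFACT_CLASSES else 97, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(class_counts, duration_s=4.0, fs=250.0, snr_db=10.0, seed=0,
                     alpha_power=0.3) -> LabeledDataset:
    """Deterministic dataset with exactly the requested count per class.

    ``class_counts`` maps class label -> nonnegative count.  Per-segment
    seeds depend only on (seed, class, index), so subsets are reproducible.
    """
    segments, labels = [], []
    counts = {}
    for label, count in class_counts.items():
        if label.upper() not in CLASS_VOCABULARY:
            raise ValueError(f"unsupported class {label!r}")
        if count < 0:
            raise ValueError(f"negative count for class {label!r}")
        counts[label.upper()] = int(count)
    vocab = tuple(counts)
    for label in vocab:
        for i in range(counts[label]):
            p = SynthParams(
                class_label=label, duration_s=duration_s, fs=fs, snr_db=snr_db,
                alpha_power=alpha_power, seed=_segment_seed(seed, label, i),
            )
            segments.append(generate_artifact_segment(p))
            labels.append(label)
    return LabeledDataset(
        segments, labels, vocab,
        meta={"seed": seed, "duration_s": duration_s, "fs": fs, "snr_db": snr_db},
    )
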