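"""File-format adapters: EDF recordings, annotation CSVs, dataset cache.

EDF reading goes through mne; writing uses a small built-in EDF encoder
(16-bit, one-second data records, per-channel rates) sufficient for export
and test fixtures.  The dataset cache is an HDF5 container with datasets
``signals`` (segments x samples, float32) and ``labels`` (byte strings)
plus attributes ``fs``, ``duration_s``, ``class_vocabulary`` and ``seed``.
Annotation CSVs use the dialect ``channel,start_time,stop_time,label``
with times in seconds from recording start.
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path

import h5py
import numpy as np

from .preprocess import AnnotationInterval, RawRecording
from .segment import EEGSegment
from .synth import LabeledDataset

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("channel", "start_time", "stop_time", "label")


# ---------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------

def read_edf(path) -> RawRecording:
    """Read an EDF/EDF+ file into microvolt samples.

    Channels recorded at different rates are resampled by the reader to
    the highest rate present (a warning is logged).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    rates = _edf_channel_rates(path)
    if len(set(rates)) > 1:
        logger.warning("mixed sampling rates %s in %s: channels resampled to %g Hz",
                       sorted(set(rates)), path.name, max(rates))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise OSError(f"could not read EDF file {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return RawRecording(data_uv, float(raw.info["sfreq"]), list(raw.ch_names))


def _edf_channel_rates(path) -> list[float]:
    """Per-channel sampling rates from the EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        n_sig = int(header[252:256].decode().strip())
        duration = float(header[244:252].decode().strip())
        sig_header = fh.read(256 * n_sig)
    # field layout per signal: label 16, transducer 80, dim 8, pmin 8,
    # pmax 8, dmin 8, dmax 8, prefilter 80, samples-per-record 8
    off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * n_sig
    spr = [int(sig_header[off + 8 * i : off + 8 * (i + 1)].decode().strip())
           for i in range(n_sig)]
    return [s / duration for s in spr]


def write_edf(path, recording: RawRecording, physical_dim="uV"):
    """Minimal EDF writer: int16, 1 s data records."""
    n_chan = recording.samples.shape[0]
    write_edf_signals(path, list(recording.samples), [recording.fs] * n_chan,
                      recording.channel_labels, physical_dim)


def write_edf_signals(path, signals, rates, labels, physical_dim="uV"):
    """EDF writer supporting per-channel sampling rates (1 s records)."""
    if not (len(signals) == len(rates) == len(labels)):
        raise ValueError("signals, rates and labels must align")
    n_chan = len(signals)
    spr = []
    for r in rates:
        if abs(round(r) - r) > 1e-9:
            raise ValueError("EDF writer supports integer sampling rates only")
        spr.append(int(round(r)))
    n_rec = max(int(np.ceil(len(s) / r)) for s, r in zip(signals, spr))

    digital, pmin, pmax = [], [], []
    dmin, dmax = -32768, 32767
    for sig, r in zip(signals, spr):
        padded = np.zeros(n_rec * r)
        padded[: len(sig)] = np.asarray(sig, dtype=np.float64)
        lo, hi = np.floor(padded.min()), np.ceil(padded.max())
        if hi <= lo:
            hi = lo + 1.0
        gain = (dmax - dmin) / (hi - lo)
        digital.append(np.round(np.clip((padded - lo) * gain + dmin, dmin, dmax)).astype("<i2"))
        pmin.append(lo)
        pmax.append(hi)

    def f(value, width):
        return str(value)[:width].ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.20", 8), f("00.00.00", 8),
        f(256 * (1 + n_chan), 8), f("EDF", 44), f(n_rec, 8), f("1", 8), f(n_chan, 4),
    ])
    fields = [
        b"".join(f(lbl, 16) for lbl in labels),
        b"".join(f("", 80) for _ in range(n_chan)),
        b"".join(f(physical_dim, 8) for _ in range(n_chan)),
        b"".join(f(f"{v:.8g}"[:8], 8) for v in pmin),
        b"".join(f(f"{v:.8g}"[:8], 8) for v in pmax),
        b"".join(f(dmin, 8) for _ in range(n_chan)),
        b"".join(f(dmax, 8) for _ in range(n_chan)),
        b"".join(f("", 80) for _ in range(n_chan)),
        b"".join(f(s, 8) for s in spr),
        b"".join(f("", 32) for _ in range(n_chan)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for blob in fields:
            fh.write(blob)
        for rec in range(n_rec):
            for c in range(n_chan):
                fh.write(digital[c][rec * spr[c] : (rec + 1) * spr[c]].tobytes())


# ---------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------

def read_annotations(path, known_labels=None) -> list[AnnotationInterval]:
    """Parse ``channel,start_time,stop_time,label`` CSV into intervals.

    Labels are upper-cased; labels outside ``known_labels`` (when given)
    are kept but flagged with a warning.  Malformed rows raise with their
    line number.
    """
    path = Path(path)
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty annotation file (missing header)")
        header = [h.strip().lower() for h in header]
        try:
            cols = [header.index(c) for c in ANNOTATION_COLUMNS]
        except ValueError:
            raise ValueError(f"{path}: header must contain {ANNOTATION_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                chan = row[cols[0]].strip()
                start = float(row[cols[1]])
                stop = float(row[cols[2]])
                label = row[cols[3]].strip().upper()
                interval = AnnotationInterval(chan, start, stop, label)
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed annotation row {row!r}: {exc}") from exc
            if known_labels is not None and label not in known_labels:
                logger.warning("%s:%d: label %r not in known vocabulary", path, lineno, label)
            out.append(interval)
    return out


def write_annotations(path, intervals):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_COLUMNS)
        for iv in intervals:
            writer.writerow([iv.channel_label, iv.start_s, iv.stop_s, iv.label])


def convert_tuar_csv(path, label_map=None) -> list[AnnotationInterval]:
    """Adapter for TUAR-style CSVs: extra columns are tolerated; only the
    channel/start/stop/label columns (by name) are used."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    aliases = {"channel": ["channel", "channel_label"],
               "start_time": ["start_time", "start", "start_time_s"],
               "stop_time": ["stop_time", "stop", "stop_time_s", "end_time"],
               "label": ["label", "artifact_label", "class"]}
    picked = {}
    for want, names in aliases.items():
        for name in names:
            if name in df.columns:
                picked[want] = name
                break
        else:
            raise ValueError(f"{path}: no column for {want!r} (searched {names})")
    out = []
    for _, row in df.iterrows():
        label = str(row[picked["label"]]).strip().upper()
        if label_map:
            label = label_map.get(label, label)
        out.append(AnnotationInterval(str(row[picked["channel"]]).strip(),
                                      float(row[picked["start_time"]]),
                                      float(row[picked["stop_time"]]), label))
    return out


# ---------------------------------------------------------------------
# dataset cache
# ---------------------------------------------------------------------

def save_dataset(path, dataset: LabeledDataset, fingerprint=None):
    """Write the segment cache (HDF5) with full reconstruction metadata."""
    signals = dataset.signal_matrix()
    with h5py.File(path, "w") as h5:
        h5.create_dataset("signals", data=signals, dtype="float32")
        h5.create_dataset("labels", data=np.array(dataset.labels, dtype="S16"))
        h5.attrs["fs"] = dataset.fs
        h5.attrs["duration_s"] = signals.shape[1] / dataset.fs
        h5.attrs["class_vocabulary"] = [c.encode() for c in dataset.class_vocabulary]
        h5.attrs["seed"] = int(dataset.meta.get("seed", -1))
        if fingerprint:
            h5.attrs["config_fingerprint"] = fingerprint


def load_dataset(path) -> LabeledDataset:
    with h5py.File(path, "r") as h5:
        signals = h5["signals"][...]
        labels = [l.decode() for l in h5["labels"][...]]
        fs = float(h5.attrs["fs"])
        vocab = tuple(v.decode() if isinstance(v, bytes) else str(v)
                      for v in h5.attrs["class_vocabulary"])
        seed = int(h5.attrs.get("seed", -1))
    segments = [EEGSegment(row, fs, label=lab, source={"cache": str(path), "index": i})
                for i, (row, lab) in enumerate(zip(signals, labels))]
    return LabeledDataset(segments, labels, vocab, meta={"seed": seed})


def export_dataset_edf(path_edf, path_csv, dataset: LabeledDataset):
    """Concatenate segments into one EDF channel + aligned annotation CSV."""
    signals = dataset.signal_matrix()
    fs = dataset.fs
    concat = signals.reshape(-1)
    rec = RawRecording(concat[None, :], fs, ["SYNTH"])
    write_edf(path_edf, rec)
    seg_s = signals.shape[1] / fs
    intervals = [AnnotationInterval("SYNTH", i * seg_s, (i + 1) * seg_s, lab)
                 for i, lab in enumerate(dataset.labels)]
    write_annotations(path_csv, intervals)
    return intervals
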