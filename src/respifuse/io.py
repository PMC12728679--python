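"""Readers and writers for the pipeline's on-disk formats.

* audio: 16-bit mono WAV (via :mod:`scipy.io.wavfile`)
* fiber: delimited text — a header line ``#subject_id,rate_hz`` followed by
  one sample per line
* feature tables: delimited text with a header row; first column
  ``subject_id``, last column ``label``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import InputError, SchemaError
from .records import FeatureTable, SignalRecord


def write_wav(path: str | Path, record: SignalRecord) -> None:
    """Write a signal as 16-bit mono WAV, peak-normalized to avoid clipping."""
    x = record.samples
    peak = np.max(np.abs(x))
    scale = 0.95 / peak if peak > 0 else 1.0
    data = np.round(x * scale * 32767).astype(np.int16)
    wavfile.write(str(path), int(round(record.rate)), data)


def read_wav(path: str | Path, subject_id: str | None = None) -> SignalRecord:
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483647.0
    else:
        samples = data.astype(float)
    sid = subject_id if subject_id is not None else Path(path).stem
    return SignalRecord(sid, "audio", float(rate), samples)


def write_fiber(path: str | Path, record: SignalRecord) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{record.subject_id},{record.rate:g}\n")
        np.savetxt(fh, record.samples, fmt="%.9g")


def read_fiber(path: str | Path) -> SignalRecord:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#") or "," not in header:
            raise InputError(f"{path}: missing '#subject_id,rate_hz' header")
        sid, rate_s = header[1:].split(",", 1)
        samples = np.loadtxt(fh, dtype=float, ndmin=1)
    return SignalRecord(sid, "fiber", float(rate_s), samples)


def write_feature_table(path: str | Path, table: FeatureTable,
                        sep: str = ",") -> None:
    frame = table.to_frame()
    frame.index.name = "subject_id"
    frame.to_csv(path, sep=sep)


def read_feature_table(path: str | Path, sep: str = ",") -> FeatureTable:
    frame = pd.read_csv(path, sep=sep, index_col="subject_id")
    if "label" not in frame.columns:
        raise SchemaError(f"{path}: no 'label' column")
    return FeatureTable(frame)


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
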