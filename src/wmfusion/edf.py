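"""Minimal EDF (European Data Format) reader and writer.

Supports continuous multi-channel recordings with one sampling rate, which
is all the pipeline needs to exchange EEG with other tools.  The writer
emits plain EDF (1-second data records, 16-bit samples, per-channel
physical scaling in µV); the reader parses the same subset.  Recordings
whose length is not a whole number of records are zero-padded on write.
"""

from __future__ import annotations

import numpy as np

from .eeg_clean import EEGRecording

__all__ = ["write_edf", "read_edf"]


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as EDF with 1 s data records.

    The sampling rate must be a positive integer; the last record is
    zero-padded when the recording length is not a whole second.
    """
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    data = np.zeros((n_ch, n_records * fs))
    data[:, : rec.n_samples] = rec.data
    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1e-6)
    dig_max = 32767
    scale = phys_max / dig_max
    header = b""
    header += _field("0", 8)
    header += _field("X X X X", 80)
    header += _field(f"Startdate X X X X ref:{rec.reference}", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("", 44)
    header += _field(str(n_records), 8)
    header += _field("1", 8)
    header += _field(str(n_ch), 4)
    header += b"".join(_field(lab, 16) for lab in rec.labels)
    header += b"".join(_field("EEG", 80) for _ in range(n_ch))
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_field(str(-dig_max), 8) for _ in range(n_ch))
    header += b"".join(_field(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))
    header += b"".join(_field(str(fs), 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))
    digital = np.clip(np.round(data / scale[:, None]), -dig_max, dig_max).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            f.write(block.tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF file with a single common sampling rate."""
    with open(path, "rb") as f:
        head = f.read(256)
        n_records = int(head[236:244].decode().strip())
        record_s = float(head[244:252].decode().strip())
        n_ch = int(head[252:256].decode().strip())
        sig = f.read(256 * n_ch)
        pos = 0

        def take(width):
            nonlocal pos
            out = [
                sig[pos + i * width : pos + (i + 1) * width].decode().strip()
                for i in range(n_ch)
            ]
            pos += width * n_ch
            return out

        labels = take(16)
        take(80)  # transducer
        take(8)  # dimension
        phys_min = np.array([float(x) for x in take(8)])
        phys_max = np.array([float(x) for x in take(8)])
        dig_min = np.array([float(x) for x in take(8)])
        dig_max = np.array([float(x) for x in take(8)])
        take(80)  # prefiltering
        spr = np.array([int(x) for x in take(8)])
        if len(set(spr.tolist())) != 1:
            raise ValueError("mixed per-channel sampling rates are not supported")
        fs = spr[0] / record_s
        raw = np.frombuffer(f.read(), dtype="<i2")
    per_rec = spr[0]
    raw = raw[: n_records * n_ch * per_rec].reshape(n_records, n_ch, per_rec)
    digital = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_max - gain * dig_max
    data = digital * gain[:, None] + offset[:, None]
    return EEGRecording(data=data, fs=float(fs), labels=labels, reference="original")
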