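"""Minimal EDF (European Data Format) writer/reader.

Supports the subset this package needs: continuous multichannel records with
one common integer sampling rate, 1-second data records, 16-bit samples with
per-channel physical scaling.  The header date is fixed so that rewriting
the same data yields byte-identical files.
"""

from __future__ import annotations

import numpy as np

_HEADER_DATE = "01.01.00"
_HEADER_TIME = "00.00.00"


def _field(value, width: int) -> bytes:
    text = str(value)
    if len(text) > width:
        raise ValueError(f"EDF field {text!r} exceeds {width} characters")
    return text.ljust(width).encode("ascii")


def _num_field(value: float, width: int) -> bytes:
    for fmt in (f"{{:.{width - 2}g}}", "{:.3g}", "{:.2g}"):
        text = fmt.format(float(value))
        if len(text) <= width:
            return text.ljust(width).encode("ascii")
    raise ValueError(f"cannot fit {value} in {width} EDF characters")


def write_edf(path, samples: np.ndarray, fs: float, channel_labels,
              patient_id: str = "X") -> None:
    """Write a (n_channels x n_samples) float array as an EDF file.

    ``fs`` must be a positive integer and the per-channel length a multiple
    of ``fs`` (whole seconds), giving 1-second data records.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (channels x samples)")
    n_channels, n_samples = samples.shape
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = round(fs)
    if n_samples % fs != 0:
        raise ValueError("record length must be a whole number of seconds")
    n_records = n_samples // fs

    # per-channel physical scaling onto the int16 range
    phys_max = np.maximum(np.abs(samples).max(axis=1), 1e-6)
    digital = np.empty((n_channels, n_samples), dtype="<i2")
    phys_fields = []
    for ch in range(n_channels):
        pmax_txt = _num_field(phys_max[ch], 8)
        pmax = float(pmax_txt.decode().strip())
        pmax = max(pmax, phys_max[ch])  # never clip due to text rounding
        phys_fields.append((-pmax, pmax))
        digital[ch] = np.clip(
            np.round(samples[ch] / pmax * 32767), -32768, 32767
        ).astype("<i2")

    header_bytes = 256 + 256 * n_channels
    parts = [
        _field("0", 8),
        _field(patient_id, 80),
        _field("neurospect", 80),
        _field(_HEADER_DATE, 8),
        _field(_HEADER_TIME, 8),
        _field(header_bytes, 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),  # record duration, seconds
        _field(n_channels, 4),
    ]
    labels = [str(lbl) for lbl in channel_labels]
    parts += [_field(lbl, 16) for lbl in labels]
    parts += [_field("", 80) for _ in labels]                      # transducer
    parts += [_field("uV", 8) for _ in labels]                     # physical dim
    parts += [_num_field(lo, 8) for lo, _ in phys_fields]          # phys min
    parts += [_num_field(hi, 8) for _, hi in phys_fields]          # phys max
    parts += [_field(-32768, 8) for _ in labels]                   # dig min
    parts += [_field(32767, 8) for _ in labels]                    # dig max
    parts += [_field("", 80) for _ in labels]                      # prefilter
    parts += [_field(fs, 8) for _ in labels]                       # samples/record
    parts += [_field("", 32) for _ in labels]                      # reserved

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        # data records: per second, each channel's fs samples in sequence
        blocks = digital.reshape(n_channels, n_records, fs)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (samples, fs, channel_labels)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256 or head[:8].strip() != b"0":
            raise ValueError(f"{path}: not an EDF file")
        n_records = int(head[236:244])
        record_duration = float(head[244:252])
        n_channels = int(head[252:256])
        sig = fh.read(256 * n_channels)

        def col(offset, width):
            base = offset * n_channels
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_channels)
            ]

        labels = col(0, 16)
        phys_min = np.array([float(v) for v in col(16 + 80 + 8, 8)])
        phys_max = np.array([float(v) for v in col(16 + 80 + 8 + 8, 8)])
        dig_min = np.array([float(v) for v in col(16 + 80 + 8 + 16, 8)])
        dig_max = np.array([float(v) for v in col(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in col(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError(f"{path}: mixed per-channel sampling rates unsupported")
        spr0 = spr[0]
        raw = np.frombuffer(fh.read(), dtype="<i2")

    expected = n_records * n_channels * spr0
    if raw.size != expected:
        raise ValueError(f"{path}: truncated data ({raw.size} of {expected} samples)")
    blocks = raw.reshape(n_records, n_channels, spr0)
    digital = blocks.transpose(1, 0, 2).reshape(n_channels, n_records * spr0)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    samples = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
    fs = spr0 / record_duration
    return samples, fs, labels
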