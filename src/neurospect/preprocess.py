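"""Record conditioning: integer-factor decimation to 256 Hz and a fixed
time-window crop (default 60-240 s of a 300 s record)."""

from __future__ import annotations

from dataclasses import dataclass, replace as _replace

import numpy as np
from scipy import signal

from .records import EEGRecord


class UnsupportedRatioError(ValueError):
    """Resampling ratio is not a positive integer."""


class UpsamplingNotSupportedError(ValueError):
    """Target rate exceeds the record's rate."""


class WindowOutOfRangeError(ValueError):
    """Requested window extends beyond the record."""


@dataclass(frozen=True)
class WindowSpec:
    """Retained time window, in seconds, plus the target sampling rate."""

    start: float = 60.0
    end: float = 240.0
    target_fs: float = 256.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")
        if self.target_fs <= 0:
            raise ValueError("target_fs must be positive")


def resample_record(record: EEGRecord, target_fs: float) -> EEGRecord:
    """Decimate a record to ``target_fs`` after zero-phase anti-alias filtering.

    Only integer downsampling factors are supported (the pipeline needs only
    1024 -> 256); the anti-alias filter is the standard 8th-order Chebyshev-I
    applied forward-backward.  A record already at ``target_fs`` is returned
    unchanged.
    """
    if target_fs > record.fs:
        raise UpsamplingNotSupportedError(
            f"cannot resample {record.fs} Hz up to {target_fs} Hz"
        )
    ratio = record.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise UnsupportedRatioError(
            f"{record.fs} Hz -> {target_fs} Hz is not an integer factor"
        )
    q = round(ratio)
    if q == 1:
        return record
    decimated = signal.decimate(record.samples, q, ftype="iir", axis=1, zero_phase=True)
    return _replace(record, samples=np.ascontiguousarray(decimated), fs=target_fs)


def extract_window(record: EEGRecord, window: WindowSpec) -> EEGRecord:
    """Crop the half-open window ``[start, end)`` seconds (0-based samples).

    The output has exactly ``(end - start) * fs`` samples per channel.
    """
    i0 = round(window.start * record.fs)
    i1 = round(window.end * record.fs)
    if i1 > record.n_samples:
        raise WindowOutOfRangeError(
            f"window end {window.end} s needs {i1} samples but record has "
            f"{record.n_samples}"
        )
    return _replace(record, samples=record.samples[:, i0:i1].copy())


def preprocess_record(record: EEGRecord, window: WindowSpec | None = None) -> EEGRecord:
    """Resample to ``window.target_fs`` then crop to ``[start, end)``."""
    window = window or WindowSpec()
    return extract_window(resample_record(record, window.target_fs), window)
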