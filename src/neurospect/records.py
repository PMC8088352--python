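"""Core data container for multichannel EEG records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: 19-electrode subset of the international 10-20 montage.
MONTAGE_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Class labels: 1 = mild cognitive impairment, 2 = Alzheimer's disease,
#: 3 = healthy control.
CLASS_LABELS = (1, 2, 3)
CLASS_NAMES = {1: "MCI", 2: "AD", 3: "HC"}


@dataclass
class EEGRecord:
    """One subject's multichannel EEG signal.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, microvolt scale.
    fs
        Sampling rate in samples per second.
    channel_labels
        One label per channel (10-20 names for the default montage).
    subject_id
        Free-form subject identifier.
    class_label
        1 (MCI), 2 (AD), 3 (HC), or ``None`` when unknown.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = field(default=MONTAGE_10_20)
    subject_id: str = ""
    class_label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_channels, n_samples) array")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[0]} channels"
            )
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be in {CLASS_LABELS} or None")
        self.channel_labels = tuple(self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs
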