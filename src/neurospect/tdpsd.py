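"""Time-domain spectral-moment descriptors.

Seven per-channel features are computed from a signal's root-squared spectral
moments of orders 0, 2 and 4.  By Parseval's theorem and the Fourier
differentiation property, these moments are obtained directly in the time
domain: the zero-order moment from the squared samples, the higher even
moments from squared first and second differences.  A power transform
``m = m_bar**lam / lam`` (default ``lam = 0.1``) compresses the moments
before the log-domain feature ratios are formed:

f1  log zero-order moment (overall power)
f2  log distance between zero- and second-order moments
f3  log distance between zero- and fourth-order moments
f4  sparseness (energy concentration; 0 for a constant signal)
f5  irregularity factor (zero crossings over peaks, via m2 / sqrt(m0*m4))
f6  coefficient of variation (std over |mean|)
f7  Teager energy (sum of x[j]^2 - x[j-1]*x[j+1])

Every logarithm takes ``|argument| + eps`` and every ratio denominator is
floored at ``eps`` so that all outputs are finite for any finite input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import CLASS_LABELS, EEGRecord

DEFAULT_LAMBDA = 0.1
DEFAULT_EPSILON = 1e-12

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7")
N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class RawMoments:
    """Un-normalized root-squared spectral moments of one channel."""

    m0_bar: float
    m2_bar: float
    m4_bar: float

    def __post_init__(self) -> None:
        for name in ("m0_bar", "m2_bar", "m4_bar"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class NormalizedMoments:
    """Power-transformed moments ``m = m_bar**lam / lam``."""

    m0: float
    m2: float
    m4: float
    lam: float


@dataclass(frozen=True)
class FeatureVector:
    """The seven log-domain descriptors for one signal."""

    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    epsilon: float = DEFAULT_EPSILON
    degenerate: bool = False  # all-zero input: entries are eps-floor values

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4,
                         self.f5, self.f6, self.f7])


def diff_series(x: np.ndarray, order: int) -> np.ndarray:
    """First (``order=1``) or second (``order=2``) finite differences.

    Each differentiation shortens the sequence by one sample; sums over
    differences therefore run over valid indices only.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    x = np.asarray(x, dtype=np.float64)
    if x.size <= order:
        raise ValueError(f"need more than {order} samples, got {x.size}")
    return np.diff(x, n=order)


def raw_moments(x: np.ndarray) -> RawMoments:
    """Root-squared moments of orders 0, 2, 4 from the time domain.

    ``m0_bar = sqrt(sum(x^2))`` equals, by Parseval's theorem, the square
    root of the mean power-spectrum mass; ``m2_bar`` and ``m4_bar`` apply the
    same to first and second differences.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    m0 = float(np.sqrt(np.sum(x**2)))
    m2 = float(np.sqrt(np.sum(np.diff(x) ** 2)))
    m4 = float(np.sqrt(np.sum(np.diff(x, n=2) ** 2)))
    return RawMoments(m0, m2, m4)


def power_transform(m: RawMoments, lam: float = DEFAULT_LAMBDA) -> NormalizedMoments:
    """Compress moments as ``m_bar**lam / lam``; zero maps to zero."""
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")

    def _t(v: float) -> float:
        return 0.0 if v == 0.0 else v**lam / lam

    return NormalizedMoments(_t(m.m0_bar), _t(m.m2_bar), _t(m.m4_bar), lam)


def _safe_log(arg: float, eps: float) -> float:
    return float(np.log(abs(arg) + eps))


def _safe_ratio(num: float, den: float, eps: float) -> float:
    return num / max(abs(den), eps if eps > 0 else np.finfo(float).tiny)


def extract_features(
    x: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    eps: float = DEFAULT_EPSILON,
) -> FeatureVector:
    """Compute the seven descriptors of one signal.

    An all-zero signal yields the eps-floor feature values with
    ``degenerate=True`` rather than raising.
    """
    x = np.asarray(x, dtype=np.float64)
    moments = raw_moments(x)
    nm = power_transform(moments, lam)
    m0, m2, m4 = nm.m0, nm.m2, nm.m4
    degenerate = moments.m0_bar == 0.0

    f1 = _safe_log(m0, eps)
    f2 = _safe_log(m0 - m2, eps)
    f3 = _safe_log(m0 - m4, eps)

    sparseness_den = np.sqrt(abs(m0 - m2)) * np.sqrt(abs(m0 - m4))
    f4 = _safe_log(_safe_ratio(m0, sparseness_den, eps), eps)

    irregularity_den = np.sqrt(m0 * m4)
    f5 = _safe_log(_safe_ratio(m2, irregularity_den, eps), eps)

    mean = float(np.mean(x))
    std = float(np.std(x))
    f6 = _safe_log(_safe_ratio(std, mean, eps), eps)

    teager = float(np.sum(x[1:-1] ** 2 - x[:-2] * x[2:]))
    f7 = _safe_log(teager, eps)

    return FeatureVector(f1, f2, f3, f4, f5, f6, f7,
                         epsilon=eps, degenerate=degenerate)


def normalize_m0_across_channels(m0_values: np.ndarray) -> np.ndarray:
    """Divide each channel's zero-order moment by the sum over channels."""
    m0_values = np.asarray(m0_values, dtype=np.float64)
    if m0_values.size < 1:
        raise ValueError("need at least one channel")
    if np.any(m0_values < 0):
        raise ValueError("zero-order moments must be nonnegative")
    total = m0_values.sum()
    if total <= 0:
        raise ValueError("cannot normalize all-zero moments")
    return m0_values / total


def subject_features(
    record: EEGRecord,
    aggregation: str = "mean",
    lam: float = DEFAULT_LAMBDA,
    eps: float = DEFAULT_EPSILON,
) -> np.ndarray:
    """Per-subject features: one 7-vector (``mean``) or a 7 x n_channels
    matrix (``concat``) from per-channel descriptors."""
    if aggregation not in ("mean", "concat"):
        raise ValueError(f"aggregation must be 'mean' or 'concat', got {aggregation!r}")
    per_channel = np.column_stack(
        [extract_features(ch, lam=lam, eps=eps).as_array() for ch in record.samples]
    )
    if aggregation == "concat":
        return per_channel
    return per_channel.mean(axis=1)


@dataclass
class FeatureTable:
    """7 x N feature matrix with per-column class labels and subject ids."""

    matrix: np.ndarray
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != N_FEATURES:
            raise ValueError(f"matrix must be {N_FEATURES} x N")
        n = self.matrix.shape[1]
        if self.labels.shape != (n,) or len(self.subject_ids) != n:
            raise ValueError("labels and subject_ids must match column count")
        if not np.all(np.isin(self.labels, CLASS_LABELS)):
            raise ValueError(f"labels must be in {CLASS_LABELS}")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[1]

    def select(self, indices: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.matrix[:, indices],
            self.labels[indices],
            [self.subject_ids[i] for i in indices],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix.T, columns=list(FEATURE_NAMES))
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(
            df[list(FEATURE_NAMES)].to_numpy().T,
            df["label"].to_numpy(),
            df["subject_id"].astype(str).tolist(),
        )


def features_from_records(
    records,
    aggregation: str = "mean",
    lam: float = DEFAULT_LAMBDA,
    eps: float = DEFAULT_EPSILON,
) -> FeatureTable:
    """Assemble a FeatureTable from an iterable of labelled records.

    Accepts any iterable (including a lazy generator, so full-size cohorts
    never need to be held in memory at once).  Requires ``mean`` aggregation
    so each subject contributes exactly one 7-vector column.
    """
    if aggregation != "mean":
        raise ValueError("feature tables require one 7-vector per subject (mean)")
    columns, labels, ids = [], [], []
    for record in records:
        if record.class_label is None:
            raise ValueError(f"record {record.subject_id!r} has no class label")
        columns.append(subject_features(record, aggregation, lam=lam, eps=eps))
        labels.append(record.class_label)
        ids.append(record.subject_id)
    if not columns:
        raise ValueError("no records supplied")
    return FeatureTable(np.column_stack(columns), np.array(labels), ids)
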