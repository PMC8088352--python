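"""Synthetic three-class EEG cohorts with controllable band-power structure.

Records are built as a sum of band-limited Gaussian noise components (one per
canonical EEG band, scaled to the class's relative band weights) mixed with a
1/f-shaped background, so that the class contrast downstream stages rely on
(slow-wave excess in AD, alpha dominance in controls) is present by
construction and every stage of the pipeline is testable without clinical
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from ._seeding import derive_seed
from .records import CLASS_LABELS, CLASS_NAMES, MONTAGE_10_20, EEGRecord

#: Canonical EEG frequency bands in Hz.  The gamma band extends to Nyquist.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.1, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, np.inf),
}
BAND_NAMES = tuple(BANDS)

#: Fraction of a channel's variance contributed by a source shared across
#: channels (real resting EEG channels co-vary; a single mixing knob keeps
#: that testable without a head model).
COMMON_SOURCE_MIXING = 0.3

#: Target root-mean-square amplitude in microvolts before per-class scaling.
BASE_RMS_UV = 50.0

#: Dirichlet concentration for per-subject band-weight jitter.
SUBJECT_JITTER_CONCENTRATION = 100.0

#: Relative log-std of the per-subject amplitude jitter.
AMPLITUDE_JITTER_SIGMA = 0.05


class InvalidSpecError(ValueError):
    """Raised when a cohort/profile specification is internally inconsistent."""


@dataclass(frozen=True)
class ClassSpectralProfile:
    """Relative band-power profile of one diagnostic class.

    ``band_weights`` maps band name -> relative power; weights must be
    nonnegative and sum to 1.  ``pink_noise_fraction`` is the variance share
    of the 1/f background.  ``amplitude_factor`` scales the overall RMS and
    encodes the class's gross power difference (slow-wave EEG runs larger).
    """

    class_label: int
    band_weights: dict[str, float]
    pink_noise_fraction: float = 0.15
    amplitude_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise InvalidSpecError(f"class_label must be in {CLASS_LABELS}")
        unknown = set(self.band_weights) - set(BANDS)
        if unknown:
            raise InvalidSpecError(f"unknown bands: {sorted(unknown)}")
        w = np.array([self.band_weights.get(b, 0.0) for b in BAND_NAMES])
        if np.any(w < 0):
            raise InvalidSpecError("band_weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidSpecError(f"band_weights must sum to 1, got {w.sum()!r}")
        if not 0.0 <= self.pink_noise_fraction <= 1.0:
            raise InvalidSpecError("pink_noise_fraction must lie in [0, 1]")
        if self.amplitude_factor <= 0:
            raise InvalidSpecError("amplitude_factor must be positive")

    def weights_array(self) -> np.ndarray:
        return np.array([self.band_weights.get(b, 0.0) for b in BAND_NAMES])


def default_profiles() -> dict[int, ClassSpectralProfile]:
    """Well-separated default profiles for the three classes.

    AD shows the strongest slow-wave (delta+theta) excess with suppressed
    alpha, HC is alpha-dominant, MCI sits in between.  The exact numbers are
    calibrated for downstream testability, not fitted to any population.
    """
    return {
        1: ClassSpectralProfile(  # MCI: intermediate slowing
            class_label=1,
            band_weights={"delta": 0.25, "theta": 0.20, "alpha": 0.27,
                          "beta": 0.18, "gamma": 0.10},
            amplitude_factor=1.0,
        ),
        2: ClassSpectralProfile(  # AD: elevated delta/theta, reduced alpha
            class_label=2,
            band_weights={"delta": 0.40, "theta": 0.27, "alpha": 0.11,
                          "beta": 0.13, "gamma": 0.09},
            amplitude_factor=1.4,
        ),
        3: ClassSpectralProfile(  # HC: alpha-dominant
            class_label=3,
            band_weights={"delta": 0.10, "theta": 0.11, "alpha": 0.48,
                          "beta": 0.21, "gamma": 0.10},
            amplitude_factor=0.7,
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Geometry and randomness of a synthetic cohort."""

    n_per_class: int = 64
    n_channels: int = 19
    duration: float = 300.0
    fs: float = 256.0
    seed: int = 0
    profiles: dict[int, ClassSpectralProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise InvalidSpecError("n_per_class must be >= 1")
        if self.n_channels < 1:
            raise InvalidSpecError("n_channels must be >= 1")
        if self.fs <= 0:
            raise InvalidSpecError("fs must be positive")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise InvalidSpecError(
                f"duration * fs must be a positive integer sample count, got {n}"
            )
        if set(self.profiles) != set(CLASS_LABELS):
            raise InvalidSpecError(f"profiles must cover classes {CLASS_LABELS}")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)

    def channel_labels(self) -> tuple[str, ...]:
        if self.n_channels <= len(MONTAGE_10_20):
            return MONTAGE_10_20[: self.n_channels]
        extra = tuple(f"EXT{i}" for i in range(self.n_channels - len(MONTAGE_10_20)))
        return MONTAGE_10_20 + extra


def _band_sos(band: tuple[float, float], fs: float) -> np.ndarray:
    """4th-order Butterworth section for one band (highpass for gamma)."""
    nyq = fs / 2.0
    low, high = band
    if low >= nyq:
        raise InvalidSpecError(f"band edge {low} Hz is at or above Nyquist ({nyq} Hz)")
    if not np.isfinite(high) or high >= nyq:
        return signal.butter(4, low, btype="highpass", fs=fs, output="sos")
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-power noise via spectral shaping, unit variance per row."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 -> power ~ 1/f
    out = np.fft.irfft(spec * scale, n=n, axis=1)
    return out / out.std(axis=1, keepdims=True)


def _jitter_weights(rng: np.random.Generator, weights: np.ndarray) -> np.ndarray:
    alpha = np.maximum(weights, 1e-8) * SUBJECT_JITTER_CONCENTRATION
    return rng.dirichlet(alpha)


def generate_record(
    profile: ClassSpectralProfile, spec: CohortSpec, subject_seed: int,
    subject_id: str = "",
) -> EEGRecord:
    """Generate one subject's multichannel record.

    Deterministic given ``(profile, spec, subject_seed)``: the same inputs
    produce bitwise-identical samples.
    """
    for band, weight in zip(BANDS.values(), profile.weights_array()):
        if weight > 0 and band[0] >= spec.fs / 2.0:
            raise InvalidSpecError(
                f"band edge {band[0]} Hz not below Nyquist {spec.fs / 2.0} Hz"
            )

    rng = np.random.default_rng(subject_seed)
    n = spec.n_samples
    n_sources = spec.n_channels + 1  # independent channels + one common source

    weights = _jitter_weights(rng, profile.weights_array())

    banded = np.zeros((n_sources, n))
    for band, weight in zip(BANDS.values(), weights):
        if weight <= 0:
            continue
        sos = _band_sos(band, spec.fs)
        component = signal.sosfiltfilt(sos, rng.standard_normal((n_sources, n)), axis=1)
        component /= component.std(axis=1, keepdims=True)
        banded += np.sqrt(weight) * component
    banded /= banded.std(axis=1, keepdims=True)

    p = profile.pink_noise_fraction
    if p > 0:
        pink = _pink_noise(rng, (n_sources, n))
        sources = np.sqrt(1.0 - p) * banded + np.sqrt(p) * pink
    else:
        sources = banded

    own, common = sources[:-1], sources[-1]
    m = COMMON_SOURCE_MIXING
    channels = np.sqrt(1.0 - m**2) * own + m * common

    amp = BASE_RMS_UV * profile.amplitude_factor
    amp *= np.exp(rng.normal(0.0, AMPLITUDE_JITTER_SIGMA))
    channels *= amp / np.sqrt(np.mean(channels**2))

    return EEGRecord(
        samples=channels,
        fs=spec.fs,
        channel_labels=spec.channel_labels(),
        subject_id=subject_id,
        class_label=profile.class_label,
    )


def iter_cohort(spec: CohortSpec):
    """Yield the cohort's records one at a time (memory-friendly).

    Per-subject seeds are derived deterministically from ``spec.seed``, so
    any record can be regenerated in isolation.
    """
    for label in CLASS_LABELS:
        profile = spec.profiles[label]
        for i in range(spec.n_per_class):
            subject_seed = derive_seed(spec.seed, label, i)
            subject_id = f"sub-{CLASS_NAMES[label]}-{i:03d}"
            yield generate_record(profile, spec, subject_seed, subject_id=subject_id)


def generate_cohort(spec: CohortSpec) -> list[EEGRecord]:
    """Generate ``3 * n_per_class`` labelled records (classes 1, 2, 3)."""
    return list(iter_cohort(spec))


def with_profiles(spec: CohortSpec, profiles: dict[int, ClassSpectralProfile]) -> CohortSpec:
    return replace(spec, profiles=profiles)
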