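"""File formats and pipeline configuration.

Cohorts are stored as one signal file per subject (EDF or plain CSV,
channels x samples) plus a manifest CSV mapping subject_id / class label /
path / rate / channel count.  Feature tables, ROC points and summary tables
are CSV; configs and reports are JSON.  Everything round-trips losslessly
enough that re-running a pipeline from the same config reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf
from ._seeding import derive_seed
from .classifiers import CNNConfig, SplitSpec
from .preprocess import WindowSpec
from .records import CLASS_LABELS, EEGRecord
from .synthetic import ClassSpectralProfile, CohortSpec, default_profiles
from .tdpsd import DEFAULT_EPSILON, DEFAULT_LAMBDA, FEATURE_NAMES, FeatureTable

MANIFEST_NAME = "manifest.csv"
MANIFEST_COLUMNS = ("subject_id", "class_label", "path", "fs", "n_channels")


# ---------------------------------------------------------------------------
# signal files

def write_signal_csv(path, record: EEGRecord) -> None:
    """Channels x samples CSV: header row with fs, one row per channel."""
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        for label, row in zip(record.channel_labels, record.samples):
            fh.write(label + "," + ",".join(f"{v:.6g}" for v in row) + "\n")


def read_signal_csv(path) -> tuple[np.ndarray, float, list[str]]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(first[len("# fs=") :])
        labels, rows = [], []
        for row_idx, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split(",")
            labels.append(cells[0])
            values = np.empty(len(cells) - 1)
            for col_idx, cell in enumerate(cells[1:], start=2):
                try:
                    values[col_idx - 2] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {row_idx}, "
                        f"column {col_idx}: {cell!r}"
                    ) from None
            rows.append(values)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: channels have unequal lengths {sorted(lengths)}")
    return np.vstack(rows), fs, labels


def write_record(path, record: EEGRecord, fmt: str) -> None:
    if fmt == "edf":
        _edf.write_edf(path, record.samples, record.fs, record.channel_labels,
                       patient_id=record.subject_id or "X")
    elif fmt == "csv":
        write_signal_csv(path, record)
    else:
        raise ValueError(f"unknown signal format {fmt!r} (use 'edf' or 'csv')")


def read_record(path, subject_id: str = "", class_label: int | None = None) -> EEGRecord:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        samples, fs, labels = _edf.read_edf(path)
    else:
        samples, fs, labels = read_signal_csv(path)
    return EEGRecord(samples=samples, fs=fs, channel_labels=tuple(labels),
                     subject_id=subject_id, class_label=class_label)


# ---------------------------------------------------------------------------
# cohort directories

def write_cohort(records, out_dir, fmt: str = "csv") -> Path:
    """Write records plus a manifest; returns the manifest path.

    ``records`` may be a lazy iterable; subjects are written one at a time.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for record in records:
        fname = f"{record.subject_id}.{fmt}"
        write_record(out_dir / fname, record, fmt)
        rows.append({
            "subject_id": record.subject_id,
            "class_label": record.class_label,
            "path": fname,
            "fs": record.fs,
            "n_channels": record.n_channels,
        })
    manifest = out_dir / MANIFEST_NAME
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def iter_signals(manifest_path):
    """Yield EEGRecords listed in a manifest, one at a time."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    base = manifest_path.parent
    for _, row in df.iterrows():
        label = int(row["class_label"])
        if label not in CLASS_LABELS:
            raise ValueError(
                f"{manifest_path}: subject {row['subject_id']} has invalid "
                f"class label {label}"
            )
        path = base / str(row["path"])
        if not path.exists():
            raise FileNotFoundError(f"{manifest_path}: signal file missing: {path}")
        record = read_record(path, subject_id=str(row["subject_id"]), class_label=label)
        if abs(record.fs - float(row["fs"])) > 1e-6:
            raise ValueError(
                f"{path}: sampling rate {record.fs} does not match manifest "
                f"value {row['fs']}"
            )
        yield record


def read_signals(manifest_path) -> list[EEGRecord]:
    return list(iter_signals(manifest_path))


# ---------------------------------------------------------------------------
# feature tables

def write_features(path, table: FeatureTable) -> None:
    table.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def read_features(path) -> FeatureTable:
    df = pd.read_csv(path)
    needed = {"subject_id", "label", *FEATURE_NAMES}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: feature CSV missing columns {sorted(missing)}")
    return FeatureTable.from_dataframe(df)


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to run the full pipeline, JSON-round-trippable."""

    n_per_class: int = 64
    n_channels: int = 19
    duration: float = 300.0
    fs: float = 256.0
    window_start: float = 60.0
    window_end: float = 240.0
    target_fs: float = 256.0
    lam: float = DEFAULT_LAMBDA
    epsilon: float = DEFAULT_EPSILON
    aggregation: str = "mean"
    classifiers: tuple[str, ...] = ("knn", "svm", "lda", "cnn")
    knn_neighbors: int = 5
    cnn_epochs: int = 200
    cnn_learning_rate: float = 1e-3
    cnn_batch_size: int = 32
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0
    signal_format: str = "csv"
    profiles: dict | None = None  # None -> default class profiles

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["classifiers"] = list(self.classifiers)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["classifiers"] = tuple(d.get("classifiers", ("knn", "svm", "lda", "cnn")))
        return cls(**d)

    # -- derived stage objects ------------------------------------------------

    def stage_seed(self, stage: str) -> int:
        order = {"simulate": 0, "split": 1, "svm": 2, "cnn": 3, "permutation": 4}
        return derive_seed(self.seed, order[stage])

    def cohort_spec(self) -> CohortSpec:
        profiles = default_profiles()
        if self.profiles:
            profiles = {
                int(label): ClassSpectralProfile(class_label=int(label), **kwargs)
                for label, kwargs in self.profiles.items()
            }
        return CohortSpec(
            n_per_class=self.n_per_class, n_channels=self.n_channels,
            duration=self.duration, fs=self.fs,
            seed=self.stage_seed("simulate"), profiles=profiles,
        )

    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_start, self.window_end, self.target_fs)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(self.train_fraction, self.stratified,
                         seed=self.stage_seed("split"))

    def cnn_config(self) -> CNNConfig:
        return CNNConfig(epochs=self.cnn_epochs,
                         learning_rate=self.cnn_learning_rate,
                         batch_size=self.cnn_batch_size,
                         seed=self.stage_seed("cnn"))
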