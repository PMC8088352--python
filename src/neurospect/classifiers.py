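"""Model training on 7-feature tables: KNN / SVM / LDA and a small CNN.

Classical models are delegated to scikit-learn behind a uniform contract
(labels plus a 3-way probability row per subject, rows summing to 1, label
always the argmax of the row).  The CNN is a seeded numpy implementation
(see ``_cnn``) because the feature vectors are tiny and full determinism is
part of the contract.

Hyperparameters are explicit, logged defaults: KNN k=5,
RBF-kernel SVM with default regularization, LDA with automatic shrinkage on
a singular within-class covariance, CNN trained with Adam (lr 1e-3, 200
epochs, batch 32).  Features are z-scored (fit on train) for the
scale-sensitive models (KNN, SVM, CNN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import _cnn
from ._cnn import relu, softmax  # re-exported: part of this module's surface
from .records import CLASS_LABELS
from .tdpsd import FeatureTable

__all__ = [
    "SplitSpec", "CNNConfig", "TrainedModel", "split_data", "relu", "softmax",
    "train_classical", "build_and_train_cnn", "predict", "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("knn", "svm", "lda", "cnn")

_CLASSES = np.array(CLASS_LABELS)


class StratificationError(ValueError):
    """A class is too small to appear in both train and test."""


class ConfigError(ValueError):
    """Inconsistent classifier configuration."""


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: stratified 80/20 by default."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class CNNConfig:
    """Shape and optimization settings for the small CNN.

    ``conv_blocks`` lists (n_filters, kernel extent, stride); pooling
    (extent 2, stride 2) follows the blocks named in ``pool_after``.  The
    input is a 7 x 1 x 1 feature column, so pooling acts on the length axis
    only.
    """

    input_len: int = 7
    conv_blocks: tuple[tuple[int, int, int], ...] = ((16, 3, 1), (32, 3, 1))
    pool_after: tuple[int, ...] = (0,)
    pool_extent: int = 2
    hidden_units: int = 32
    dropout_rate: float = 0.5
    n_classes: int = 3
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.input_len < 1:
            raise ConfigError("input_len must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        length = self.input_len
        for i, (n_filters, kernel, stride) in enumerate(self.conv_blocks):
            if n_filters < 1 or kernel < 1 or stride != 1:
                raise ConfigError(f"conv block {i} is invalid: {(n_filters, kernel, stride)}")
            if i in self.pool_after:
                if length < self.pool_extent:
                    raise ConfigError(
                        f"pooling after block {i} needs length >= {self.pool_extent}, "
                        f"have {length}"
                    )
                length //= self.pool_extent
        if length < 1:
            raise ConfigError("layer chain collapses the signal to length 0")


@dataclass
class TrainedModel:
    """A fitted classifier with its preprocessing and provenance."""

    kind: str
    model: Any
    classes: np.ndarray
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    curves: dict | None = None  # CNN only: per-epoch accuracy / loss

    def _transform(self, x: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            return x
        return (x - self.scaler_mean) / self.scaler_std


def split_data(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint, exhaustive train/test split, stratified by class label.

    Per class, ``floor(n * train_fraction)`` subjects go to train, so the
    per-class counts deviate from exact proportionality by at most one.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = table.labels
    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratified:
        for label in np.unique(labels):
            members = np.flatnonzero(labels == label)
            if members.size < 2:
                raise StratificationError(
                    f"class {label} has {members.size} subject(s); stratified "
                    "splitting needs at least 2 per class"
                )
            perm = rng.permutation(members)
            n_train = int(np.floor(members.size * spec.train_fraction))
            n_train = min(max(n_train, 1), members.size - 1)
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
    else:
        perm = rng.permutation(table.n_subjects)
        n_train = int(np.floor(table.n_subjects * spec.train_fraction))
        n_train = min(max(n_train, 1), table.n_subjects - 1)
        train_idx = list(perm[:n_train])
        test_idx = list(perm[n_train:])
    train_idx = np.sort(np.array(train_idx))
    test_idx = np.sort(np.array(test_idx))
    return table.select(train_idx), table.select(test_idx)


def _fit_scaler(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def _check_labels(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain at least 2 classes")


def train_classical(
    kind: str,
    train: FeatureTable,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit a KNN, SVM or LDA model on a feature table."""
    if kind not in ("knn", "svm", "lda"):
        raise ConfigError(f"unknown classical kind {kind!r}")
    hyperparams = dict(hyperparams or {})
    x = train.matrix.T
    y = train.labels
    _check_labels(y)

    scaler_mean = scaler_std = None
    if kind in ("knn", "svm"):
        scaler_mean, scaler_std = _fit_scaler(x)
        x = (x - scaler_mean) / scaler_std

    if kind == "knn":
        k = int(hyperparams.pop("n_neighbors", 5))
        est = KNeighborsClassifier(n_neighbors=k, **hyperparams)
        est.fit(x, y)
        meta = {"n_neighbors": k}
    elif kind == "svm":
        est = SVC(kernel=hyperparams.pop("kernel", "rbf"), probability=True,
                  random_state=seed % 2**32, **hyperparams)
        with warnings.catch_warnings():
            # pairwise-coupled Platt probabilities are part of this module's
            # contract; silence sklearn's deprecation of the parameter spelling
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(x, y)
        meta = {"kernel": est.kernel, "C": est.C}
    else:  # lda
        est, meta = _fit_lda(x, y, hyperparams)

    meta["seed"] = seed
    return TrainedModel(kind=kind, model=est, classes=est.classes_.copy(),
                        scaler_mean=scaler_mean, scaler_std=scaler_std,
                        metadata=meta)


def _fit_lda(x: np.ndarray, y: np.ndarray, hyperparams: dict):
    # pooled within-class covariance; near-singular -> shrinkage fallback
    centered = np.concatenate([x[y == c] - x[y == c].mean(axis=0) for c in np.unique(y)])
    pooled = centered.T @ centered / max(len(x) - len(np.unique(y)), 1)
    singular = np.linalg.cond(pooled) > 1e12
    if singular:
        warnings.warn(
            "within-class covariance is singular; fitting LDA with automatic "
            "shrinkage (lsqr solver)", RuntimeWarning, stacklevel=3,
        )
        est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto", **hyperparams)
    else:
        est = LinearDiscriminantAnalysis(**hyperparams)
    est.fit(x, y)
    return est, {"shrinkage_fallback": bool(singular)}


def build_and_train_cnn(train: FeatureTable, config: CNNConfig | None = None) -> TrainedModel:
    """Train the small CNN on a feature table.

    Shape consistency is checked before any training starts.  Training is
    fully seeded: a duplicate run yields identical weights and identical
    per-epoch accuracy/loss curves (stored in ``TrainedModel.curves``).
    """
    config = config or CNNConfig()
    config.validate()
    if train.n_subjects == 0:
        raise ValueError("training table is empty")
    if train.matrix.shape[0] != config.input_len:
        raise ConfigError(
            f"config expects {config.input_len} features, table has "
            f"{train.matrix.shape[0]}"
        )
    _check_labels(train.labels)

    x = train.matrix.T
    scaler_mean, scaler_std = _fit_scaler(x)
    x = (x - scaler_mean) / scaler_std
    x3 = x[:, None, :]  # (N, 1, L)

    y_onehot = (train.labels[:, None] == _CLASSES[None, :]).astype(np.float64)

    rng = np.random.default_rng(config.seed)
    net = _cnn.SmallCNN(
        input_len=config.input_len,
        conv_blocks=config.conv_blocks,
        pool_after=set(config.pool_after),
        pool_extent=config.pool_extent,
        hidden_units=config.hidden_units,
        dropout_rate=config.dropout_rate,
        n_classes=config.n_classes,
        rng=rng,
    )
    acc, loss = _cnn.train_cnn(
        net, x3, y_onehot,
        epochs=config.epochs, learning_rate=config.learning_rate,
        batch_size=config.batch_size, rng=rng,
    )
    curves = {"epoch": np.arange(1, config.epochs + 1),
              "accuracy": acc, "loss": loss}
    return TrainedModel(kind="cnn", model=net, classes=_CLASSES.copy(),
                        scaler_mean=scaler_mean, scaler_std=scaler_std,
                        metadata={"config": config}, curves=curves)


def predict(model: TrainedModel, data: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Labels and a (N x 3) probability matrix, columns ordered 1, 2, 3.

    The returned label is always the argmax of its score row, so the two
    outputs can never disagree.
    """
    x = data.matrix.T
    if x.shape[1] != (model.scaler_mean.shape[0] if model.scaler_mean is not None
                      else x.shape[1]):
        raise ValueError("feature dimension mismatch")
    x = model._transform(x)

    scores = np.zeros((x.shape[0], len(_CLASSES)))
    if model.kind == "cnn":
        scores[:] = model.model.predict_proba(x[:, None, :])
    else:
        proba = model.model.predict_proba(x)
        for j, c in enumerate(model.classes):
            scores[:, np.flatnonzero(_CLASSES == c)[0]] = proba[:, j]
    scores /= scores.sum(axis=1, keepdims=True)
    labels = _CLASSES[scores.argmax(axis=1)]
    return labels, scores
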