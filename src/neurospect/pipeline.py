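"""End-to-end run: simulate -> preprocess -> extract -> train -> evaluate."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import evaluation as ev
from . import io as nio
from .preprocess import preprocess_record
from .records import CLASS_NAMES
from .synthetic import iter_cohort
from .tdpsd import features_from_records

log = logging.getLogger("neurospect")


def compute_feature_table(config: nio.PipelineConfig):
    """Simulate the cohort and extract per-subject features, streaming one
    record at a time so full-size cohorts never sit in memory at once."""
    spec = config.cohort_spec()
    window = config.window_spec()
    log.info("simulate: n_per_class=%d n_channels=%d duration=%gs fs=%g seed=%d",
             spec.n_per_class, spec.n_channels, spec.duration, spec.fs, spec.seed)
    log.info("preprocess: window [%g, %g) s at %g Hz; extract: lambda=%g eps=%g",
             window.start, window.end, window.target_fs, config.lam, config.epsilon)
    preprocessed = (preprocess_record(r, window) for r in iter_cohort(spec))
    return features_from_records(preprocessed, aggregation="mean",
                                 lam=config.lam, eps=config.epsilon)


def train_one(kind: str, train_table, config: nio.PipelineConfig):
    if kind == "cnn":
        return clf.build_and_train_cnn(train_table, config.cnn_config())
    hyper = {"n_neighbors": config.knn_neighbors} if kind == "knn" else None
    seed = config.stage_seed("svm") if kind == "svm" else 0
    return clf.train_classical(kind, train_table, hyperparams=hyper, seed=seed)


def evaluate_model(model, test_table) -> ev.EvaluationReport:
    labels, scores = clf.predict(model, test_table)
    return ev.evaluate_predictions(test_table.labels, labels, scores, model.kind)


def _write_roc_csv(path, y_true, scores) -> None:
    rows = []
    for c in (1, 2, 3):
        roc = ev.roc_one_vs_rest(y_true, scores, c)
        for thr, fpr, tpr in zip(roc.thresholds, roc.fpr, roc.tpr):
            rows.append({"class": CLASS_NAMES[c], "threshold": thr,
                         "fpr": fpr, "tpr": tpr})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def run_all(config: nio.PipelineConfig, out_dir) -> dict[str, ev.EvaluationReport]:
    """Execute the whole pipeline; writes features, per-model reports and a
    combined summary table under ``out_dir``.  Fully determined by the
    config (including its single global seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(config.to_json())

    try:
        table = compute_feature_table(config)
        nio.write_features(out_dir / "features.csv", table)
    except Exception as exc:
        raise RuntimeError(f"stage simulate/extract failed: {exc}") from exc

    try:
        train_table, test_table = clf.split_data(table, config.split_spec())
    except Exception as exc:
        raise RuntimeError(f"stage split failed: {exc}") from exc
    log.info("split: %d train / %d test (fraction %g, stratified=%s, seed=%d)",
             train_table.n_subjects, test_table.n_subjects,
             config.train_fraction, config.stratified, config.stage_seed("split"))

    reports: dict[str, ev.EvaluationReport] = {}
    summary_rows = []
    for kind in config.classifiers:
        try:
            model = train_one(kind, train_table, config)
            labels, scores = clf.predict(model, test_table)
            report = ev.evaluate_predictions(test_table.labels, labels, scores, kind)
        except Exception as exc:
            raise RuntimeError(f"stage train/evaluate ({kind}) failed: {exc}") from exc
        reports[kind] = report
        (out_dir / f"report_{kind}.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        _write_roc_csv(out_dir / f"roc_{kind}.csv", test_table.labels, scores)
        if model.curves is not None:
            pd.DataFrame(model.curves).to_csv(
                out_dir / "cnn_training_curve.csv", index=False, float_format="%.12g"
            )
        row = {"model": kind, "accuracy_pct": report.accuracy_pct,
               "macro_auc": round(report.macro_auc, 4)}
        for c, name in CLASS_NAMES.items():
            row[f"sensitivity_{name}_pct"] = report.sensitivity_pct[c]
            row[f"precision_{name}_pct"] = report.precision_pct[c]
            row[f"auc_{name}"] = round(report.auc[c], 4)
        summary_rows.append(row)
        log.info("%s: accuracy %.1f%%, macro AUC %.3f", kind,
                 report.accuracy_pct, report.macro_auc)

    pd.DataFrame(summary_rows).to_csv(out_dir / "summary.csv", index=False)
    return reports


def permutation_null_accuracy(table, config: nio.PipelineConfig, kind: str = "cnn"):
    """Test accuracy after randomly permuting training labels (chance check)."""
    rng = np.random.default_rng(config.stage_seed("permutation"))
    train_table, test_table = clf.split_data(table, config.split_spec())
    shuffled = train_table.select(np.arange(train_table.n_subjects))
    shuffled.labels = rng.permutation(shuffled.labels)
    model = train_one(kind, shuffled, config)
    labels, _ = clf.predict(model, test_table)
    return float(np.mean(labels == test_table.labels))
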