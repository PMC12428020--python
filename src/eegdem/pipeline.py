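"""End-to-end orchestration: simulate -> preprocess -> features ->
select -> optimise/train -> evaluate.

One run produces the 2 x 3 grid of evaluation reports (SVM and k-NN,
each on the full 342-feature set, the RTH-selected set and the top-50
set), a correlation report, the feature table and a manifest with the
resolved configuration, seeds and file checksums. Everything is
deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import (KNN_K_SPACE, SVM_C_SPACE, BOResult, KNNConfig,
                       SVMConfig, bayes_opt, cv_objective, knn_predict,
                       resubstitution_objective, standardize_apply,
                       standardize_fit, svm_predict, svm_train)
from .data import CLASS_ORDER, Recording, read_cohort
from .evaluate import EvaluationReport, evaluate_predictions
from .features import (FeatureConfig, FeatureMatrix, build_feature_matrix,
                       describe_features)
from .preprocess import bandpass, segment_cohort
from .selection import (CorrelationReport, select_features, subject_wise_split,
                        systematic_split, top_k)
from .synth import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

FEATURE_SETS = ("all", "selected", "top50")
CLASSIFIERS = ("svm", "knn")


@dataclass
class PipelineConfig:
    """All stage parameters of one run."""

    # input: a synthetic cohort recipe, or a directory of recordings
    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    data_dir: str | None = None

    # preprocessing
    apply_bandpass: bool = True   # no-op flag for pre-filtered input
    bandpass_low: float = 0.5
    bandpass_high: float = 45.0
    bandpass_order: int = 4
    epoch_seconds: float = 30.0
    epoch_overlap: float = 0.5

    # features
    features: FeatureConfig = field(default_factory=FeatureConfig)

    # split + selection
    train_fraction: float = 0.7
    subject_wise: bool = False    # leakage-free alternative split
    selection_method: str = "spearman"
    top_k: int = 50

    # classification
    bo_n_init: int = 5
    bo_n_iter: int = 25
    cv_folds: int = 5
    objective: str = "cv"         # "cv" | "resubstitution"
    feature_sets: tuple[str, ...] = FEATURE_SETS
    classifiers: tuple[str, ...] = CLASSIFIERS

    seed: int = 0

    @property
    def class_order(self) -> tuple[str, ...]:
        return self.features.class_order

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class ModelRun:
    """Result of one (classifier, feature set) cell."""

    classifier: str
    feature_set: str
    n_features: int
    bo: BOResult
    report: EvaluationReport

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "feature_set": self.feature_set,
            "n_features": self.n_features,
            "best_hyperparameter": {self.bo.space.name: self.bo.best_x},
            "objective_value": self.bo.best_y,
            "bo_trace": [[float(a), float(b)] for a, b in self.bo.trace],
            "evaluation": self.report.to_dict(),
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: FeatureMatrix
    split_train: np.ndarray
    split_test: np.ndarray
    correlation: CorrelationReport
    runs: dict[tuple[str, str], ModelRun]

    def accuracy(self, classifier: str, feature_set: str) -> float:
        return self.runs[(classifier, feature_set)].report.accuracy_percent


def _feature_subsets(matrix: FeatureMatrix, report: CorrelationReport,
                     config: PipelineConfig) -> dict[str, FeatureMatrix]:
    out = {}
    for fs in config.feature_sets:
        if fs == "all":
            out[fs] = matrix
        elif fs == "selected":
            out[fs] = matrix.subset_columns(report.selected_indices)
        elif fs == "top50":
            k = min(config.top_k, report.n_selected)
            if k < config.top_k:
                logger.warning("only %d features selected; top-%d set "
                               "reduced to %d", report.n_selected,
                               config.top_k, k)
            out[fs] = matrix.subset_columns(top_k(report, k))
        else:
            raise ValueError(f"unknown feature set {fs!r}")
    return out


def _optimize_and_evaluate(classifier: str, sub: FeatureMatrix,
                           train_rows: np.ndarray, test_rows: np.ndarray,
                           config: PipelineConfig, seed: int) -> ModelRun:
    X_tr = sub.values[train_rows]
    y_tr = sub.labels[train_rows]
    X_te = sub.values[test_rows]
    y_te = sub.labels[test_rows]
    order = config.class_order
    space = SVM_C_SPACE if classifier == "svm" else KNN_K_SPACE

    if config.objective == "cv":
        def objective(h):
            return cv_objective(X_tr, y_tr, classifier, h,
                                folds=config.cv_folds, seed=seed,
                                class_order=order)
    else:
        def objective(h):
            return resubstitution_objective(X_tr, y_tr, classifier, h,
                                            class_order=order)

    bo = bayes_opt(objective, space, n_iter=config.bo_n_iter,
                   n_init=config.bo_n_init, seed=seed)

    stats = standardize_fit(X_tr)
    Z_tr = standardize_apply(X_tr, stats)
    Z_te = standardize_apply(X_te, stats)
    if classifier == "svm":
        model = svm_train(Z_tr, y_tr, SVMConfig(box_constraint=bo.best_x,
                                                class_order=order))
        y_pred, scores = svm_predict(model, Z_te)
    else:
        y_pred, scores = knn_predict(Z_tr, y_tr, Z_te,
                                     KNNConfig(k=int(bo.best_x),
                                               class_order=order))
    report = evaluate_predictions(y_te, y_pred, scores, order)
    return ModelRun(classifier=classifier, feature_set="",
                    n_features=sub.values.shape[1], bo=bo, report=report)


def load_recordings(config: PipelineConfig) -> list[Recording]:
    if config.data_dir is not None:
        return read_cohort(config.data_dir)
    if config.cohort is None:
        raise ValueError("config needs either a cohort recipe or a data_dir")
    cohort = dataclasses.replace(config.cohort, seed=config.seed)
    return generate_cohort(cohort)


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis; optionally write a run directory."""
    recordings = load_recordings(config)
    if config.apply_bandpass:
        recordings = [bandpass(r, config.bandpass_low, config.bandpass_high,
                               config.bandpass_order) for r in recordings]
    epochs = segment_cohort(recordings, config.epoch_seconds,
                            config.epoch_overlap)
    if not epochs:
        raise RuntimeError("stage 'preprocess': no epochs produced "
                           "(recordings shorter than one epoch?)")
    matrix = build_feature_matrix(epochs, config.features)

    if config.subject_wise:
        split = subject_wise_split(matrix.labels, matrix.subject_ids,
                                   config.train_fraction, config.class_order)
        logger.info("split mode: SUBJECT-WISE (leakage-free)")
    else:
        split = systematic_split(matrix.labels, config.train_fraction,
                                 config.class_order)
        logger.info("split mode: epoch-level systematic (reference protocol)")

    correlation = select_features(matrix, split.train_rows,
                                  config.selection_method, config.class_order)
    subsets = _feature_subsets(matrix, correlation, config)

    runs: dict[tuple[str, str], ModelRun] = {}
    rng = np.random.default_rng(config.seed)
    for classifier in config.classifiers:
        for fs_name, sub in subsets.items():
            cell_seed = int(rng.integers(0, 2**31 - 1))
            run = _optimize_and_evaluate(classifier, sub, split.train_rows,
                                         split.test_rows, config, cell_seed)
            run.feature_set = fs_name
            runs[(classifier, fs_name)] = run
            logger.info("%s / %s (%d features): accuracy %.2f%%",
                        classifier, fs_name, run.n_features,
                        run.report.accuracy_percent)

    result = PipelineResult(config=config, matrix=matrix,
                            split_train=split.train_rows,
                            split_test=split.test_rows,
                            correlation=correlation, runs=runs)
    if out_dir is not None:
        _write_run_dir(result, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_run_dir(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "reports").mkdir(exist_ok=True)
    (out_dir / "models").mkdir(exist_ok=True)
    result.config.to_yaml(out_dir / "config.yaml")
    result.matrix.to_csv(out_dir / "features.csv")
    result.correlation.to_dataframe().to_csv(out_dir / "correlation.csv",
                                             index=False)
    (out_dir / "correlation_summary.json").write_text(
        json.dumps(result.correlation.summary(), indent=1))
    for (clf, fs), run in result.runs.items():
        stem = f"{clf}_{fs}"
        run.report.to_json(out_dir / "reports" / f"{stem}.json")
        (out_dir / "models" / f"{stem}.json").write_text(
            json.dumps({k: v for k, v in run.to_dict().items()
                        if k != "evaluation"}, indent=1))
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "seed": result.config.seed,
        "split": {"train_rows": result.split_train.tolist(),
                  "test_rows": result.split_test.tolist(),
                  "mode": "subject-wise" if result.config.subject_wise
                          else "epoch-level systematic"},
        "checksums": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


__all__ = ["PipelineConfig", "PipelineResult", "ModelRun", "run_pipeline",
           "load_recordings", "describe_features", "FEATURE_SETS",
           "CLASSIFIERS"]
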