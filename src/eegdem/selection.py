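"""Systematic train/test splitting and correlation-threshold selection.

The split is deterministic "systematic sampling": within each class,
rows are taken in stored order and every row whose 1-based position i
satisfies ``ceil(i*q) > ceil((i-1)*q)`` (q = test fraction) goes to the
test set, producing an evenly interleaved pattern with per-class test
count ``ceil(n_class * q)``.

Feature selection ranks features by the absolute correlation between
each feature column and the integer-coded class label, computed on the
training rows only (no leakage), and keeps features whose |r| strictly
exceeds the threshold RTH = mean over all features of |r|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import CLASS_ORDER
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

_CEIL_EPS = 1e-9  # guards float noise at exact integer multiples


@dataclass
class SplitIndices:
    """Row indices of a deterministic stratified train/test split."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    train_fraction: float


def _ceil(v: float) -> int:
    return math.ceil(v - _CEIL_EPS)


def systematic_split(labels: np.ndarray, train_fraction: float = 0.7,
                     class_order: tuple[str, ...] = CLASS_ORDER) -> SplitIndices:
    """Systematic stratified split on an array of row labels.

    Within each class the i-th row (1-based, stored order) is a test
    row iff ``ceil(i*q) > ceil((i-1)*q)`` with ``q = 1 -
    train_fraction``; the per-class test count is ``ceil(n * q)`` and
    is never zero.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    labels = np.asarray(labels)
    q = 1.0 - train_fraction
    train, test = [], []
    seen = [c for c in class_order if c in labels]
    seen += [c for c in pd.unique(labels) if c not in seen]
    for cls in seen:
        rows = np.flatnonzero(labels == cls)
        if rows.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        for i, r in enumerate(rows, start=1):
            if _ceil(i * q) > _ceil((i - 1) * q):
                test.append(r)
            else:
                train.append(r)
    return SplitIndices(np.array(sorted(train)), np.array(sorted(test)),
                        train_fraction)


def subject_wise_split(labels: np.ndarray, subject_ids: np.ndarray,
                       train_fraction: float = 0.7,
                       class_order: tuple[str, ...] = CLASS_ORDER) -> SplitIndices:
    """Leakage-free variant: the systematic pattern is applied to
    whole subjects within each class, so no subject contributes rows to
    both sides."""
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    subj_label = {}
    for s, l in zip(subject_ids, labels):
        subj_label.setdefault(s, l)
    subjects = np.array(list(subj_label))
    subj_split = systematic_split(np.array([subj_label[s] for s in subjects]),
                                  train_fraction, class_order)
    test_subjects = set(subjects[subj_split.test_rows])
    is_test = np.array([s in test_subjects for s in subject_ids])
    return SplitIndices(np.flatnonzero(~is_test), np.flatnonzero(is_test),
                        train_fraction)


def encode_labels(labels: np.ndarray,
                  order: tuple[str, ...] = CLASS_ORDER) -> np.ndarray:
    """Integer codes = 1-based rank of each label in *order*."""
    code = {c: i + 1 for i, c in enumerate(order)}
    try:
        return np.array([code[l] for l in labels], dtype=float)
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in class order {order}") from None


def decode_labels(codes: np.ndarray,
                  order: tuple[str, ...] = CLASS_ORDER) -> np.ndarray:
    return np.array([order[int(c) - 1] for c in codes])


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc**2) * np.sum(yc**2))
    if denom == 0:
        return float("nan")
    return float(np.dot(xc, yc) / denom)


def spearman_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    With heavily tied vectors (integer-coded labels) the midrank form
    is the operative definition; it reduces to the classical
    ``1 - 6*sum(d_i^2)/(N(N^2-1))`` when no ties exist.
    """
    return pearson_corr(rankdata(x), rankdata(y))


_CORR_FUNCS = {"pearson": pearson_corr, "spearman": spearman_corr}


@dataclass
class CorrelationReport:
    """Feature-label correlations, the RTH threshold and the survivors."""

    method: str
    coefficients: np.ndarray       # signed r per feature (NaN = missing)
    abs_coefficients: np.ndarray   # |r| with missing as 0
    threshold_rth: float
    selected_indices: list[int]    # 1-based flat indices, |r| descending
    label_encoding: dict[str, int]
    feature_names: list[str] | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.coefficients.size
        names = self.feature_names or [str(i + 1) for i in range(n)]
        sel = set(self.selected_indices)
        return pd.DataFrame({
            "flat_index": np.arange(1, n + 1),
            "feature": names,
            "r": self.coefficients,
            "abs_r": self.abs_coefficients,
            "selected": [i + 1 in sel for i in range(n)],
        })

    def summary(self) -> dict:
        return {"method": self.method, "rth": self.threshold_rth,
                "n_features": int(self.coefficients.size),
                "n_selected": self.n_selected,
                "label_encoding": self.label_encoding}


def feature_label_correlations(matrix: FeatureMatrix, rows: np.ndarray,
                               method: str = "spearman",
                               class_order: tuple[str, ...] = CLASS_ORDER
                               ) -> np.ndarray:
    """Signed correlation of every feature column with the coded label,
    computed on the given (training) rows only."""
    if method not in _CORR_FUNCS:
        raise ValueError(f"unknown correlation method {method!r}")
    fn = _CORR_FUNCS[method]
    y = encode_labels(matrix.labels[rows], class_order)
    X = matrix.values[rows]
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        out[j] = fn(X[:, j], y)
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        logger.warning("%d feature(s) with undefined correlation "
                       "(zero variance); excluded from selection", n_missing)
    return out


def threshold_and_select(coefficients: np.ndarray, method: str,
                         class_order: tuple[str, ...] = CLASS_ORDER,
                         feature_names: list[str] | None = None
                         ) -> CorrelationReport:
    """Apply the RTH rule: keep features with |r| strictly above the
    mean of |r| over all features (missing r counts as 0 and is never
    selected); survivors sorted by descending |r|, ties by ascending
    flat index."""
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if np.all(np.isnan(coefficients)):
        raise ValueError("all correlation coefficients are missing")
    abs_r = np.abs(coefficients)
    abs_r = np.where(np.isnan(abs_r), 0.0, abs_r)
    rth = float(abs_r.mean())
    candidates = [i + 1 for i in range(abs_r.size)
                  if abs_r[i] > rth and not np.isnan(coefficients[i])]
    candidates.sort(key=lambda i: (-abs_r[i - 1], i))
    return CorrelationReport(
        method=method,
        coefficients=coefficients,
        abs_coefficients=abs_r,
        threshold_rth=rth,
        selected_indices=candidates,
        label_encoding={c: i + 1 for i, c in enumerate(class_order)},
        feature_names=feature_names,
    )


def select_features(matrix: FeatureMatrix, train_rows: np.ndarray,
                    method: str = "spearman",
                    class_order: tuple[str, ...] = CLASS_ORDER
                    ) -> CorrelationReport:
    """Correlations on the training rows + RTH thresholding, in one step."""
    r = feature_label_correlations(matrix, train_rows, method, class_order)
    return threshold_and_select(r, method, class_order,
                                [str(n) for n in matrix.names])


def top_k(report: CorrelationReport, k: int = 50) -> list[int]:
    """The k highest-|r| selected features (1-based flat indices)."""
    if k > report.n_selected:
        raise ValueError(
            f"k = {k} exceeds the {report.n_selected} selected features")
    return report.selected_indices[:k]
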