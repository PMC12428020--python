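"""Classifiers and Gaussian-process Bayesian hyperparameter search.

Two classifiers: a soft-margin SVM with the degree-2 polynomial
("quadratic") kernel K(u, v) = (u.v / s^2 + 1)^2, one-vs-one multiclass
voting, and a k-nearest-neighbour rule with cosine distance
d = 1 - cos(u, v) and squared-inverse neighbour weights (class score =
sum of 1/d^2 over that class's neighbours among the k nearest).

The single free hyperparameter of each (box constraint C; neighbour
count k) is tuned by Bayesian optimisation: a Matern-5/2 Gaussian
process surrogate over the (rescaled) search domain, expected
improvement acquisition maximised on a random candidate grid, objective
= mean stratified cross-validated accuracy on the training split with
standardisation refit inside each fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.metrics.pairwise import cosine_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import CLASS_ORDER

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

@dataclass
class StandardizationStats:
    """Per-feature mean/SD from the training rows; zero-variance
    features are dropped consistently from train and test."""

    mean: np.ndarray
    std: np.ndarray
    kept_columns: np.ndarray  # indices into the original column space


def standardize_fit(train_X: np.ndarray) -> StandardizationStats:
    train_X = np.asarray(train_X, dtype=np.float64)
    if train_X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean = train_X.mean(axis=0)
    std = train_X.std(axis=0)
    kept = np.flatnonzero(std > 0)
    if kept.size < train_X.shape[1]:
        logger.warning("dropping %d zero-variance feature(s)",
                       train_X.shape[1] - kept.size)
    return StandardizationStats(mean[kept], std[kept], kept)


def standardize_apply(X: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return (X[:, stats.kept_columns] - stats.mean) / stats.std


def standardize_invert(Z: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """Inverse transform over the kept columns."""
    return Z * stats.std + stats.mean


# ---------------------------------------------------------------------------
# SVM (degree-2 polynomial kernel, one-vs-one)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVMConfig:
    box_constraint: float = 1.0
    kernel_scale: float | str = "auto"   # "auto" -> sqrt(n_features)
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if self.box_constraint <= 0:
            raise ValueError("box constraint C must be positive")


@dataclass
class SVMModel:
    estimator: SVC
    config: SVMConfig
    classes: tuple[str, ...]


def svm_train(X: np.ndarray, y: np.ndarray, config: SVMConfig) -> SVMModel:
    """Fit the quadratic-kernel SVM.

    ``kernel_scale="auto"`` means s = sqrt(n_features) after
    standardisation, giving K(u, v) = (u.v / n_features + 1)^2.
    """
    y = np.asarray(y)
    classes = [c for c in config.class_order if c in y]
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    s = (np.sqrt(X.shape[1]) if config.kernel_scale == "auto"
         else float(config.kernel_scale))
    est = SVC(C=config.box_constraint, kernel="poly", degree=2,
              gamma=1.0 / s**2, coef0=1.0,
              decision_function_shape="ovr")
    est.fit(X, y)
    return SVMModel(est, config, tuple(classes))


def svm_predict(model: SVMModel, X: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels plus per-class scores (aggregated one-vs-one
    signed distances in the model's class order), usable for ROC."""
    labels = model.estimator.predict(X)
    raw = model.estimator.decision_function(X)
    est_classes = list(model.estimator.classes_)
    if raw.ndim == 1:  # binary: expand to two-column per-class scores
        raw = np.column_stack([-raw, raw])
    order = [est_classes.index(c) for c in model.classes]
    return labels, raw[:, order]


# ---------------------------------------------------------------------------
# k-NN (cosine distance, squared-inverse weights)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")


#: Distances below this are treated as exact matches; the squared-
#: inverse weight is clipped here, which realises the infinite-weight
#: limit (zero-distance neighbours dominate and ties among them reduce
#: to a majority vote).
_D_MIN = 1e-12


def knn_predict(train_X: np.ndarray, train_y: np.ndarray, query_X: np.ndarray,
                config: KNNConfig) -> tuple[np.ndarray, np.ndarray]:
    """k-NN with cosine distance and squared-inverse weighting.

    Returns predicted labels and the per-class weight totals (columns in
    ``config.class_order``); argmax ties break by class order.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    query_X = np.asarray(query_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    if config.k > train_X.shape[0]:
        raise ValueError("k exceeds the number of training rows")
    for name, M in (("training", train_X), ("query", query_X)):
        norms = np.linalg.norm(M, axis=1)
        if np.any(norms == 0):
            bad = np.flatnonzero(norms == 0)
            raise ValueError(f"zero-norm {name} row(s) at {bad.tolist()}")
    classes = list(config.class_order)
    class_idx = {c: i for i, c in enumerate(classes)}
    unknown = set(train_y) - set(classes)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in class order")

    D = cosine_distances(query_X, train_X)
    k = config.k
    scores = np.zeros((query_X.shape[0], len(classes)))
    for i in range(query_X.shape[0]):
        nn = np.argpartition(D[i], k - 1)[:k]
        d = np.maximum(D[i][nn], _D_MIN)
        w = 1.0 / d**2
        for j, t in zip(w, nn):
            scores[i, class_idx[train_y[t]]] += j
    labels = np.array([classes[int(np.argmax(row))] for row in scores])
    return labels, scores


# ---------------------------------------------------------------------------
# Gaussian-process Bayesian optimisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """A bounded 1-D hyperparameter domain."""

    name: str
    low: float
    high: float
    log: bool = False      # optimise on log scale (e.g. box constraint C)
    integer: bool = False  # round at evaluation (e.g. neighbour count k)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low) and np.isfinite(self.high)
                and self.low < self.high):
            raise ValueError("search bounds must be finite with low < high")
        if self.log and self.low <= 0:
            raise ValueError("log-scaled bounds must be positive")

    def from_unit(self, u: float) -> float:
        """Map u in [0, 1] to the native domain."""
        if self.log:
            x = self.low * (self.high / self.low) ** u
        else:
            x = self.low + u * (self.high - self.low)
        return float(np.clip(round(x) if self.integer else x,
                             self.low, self.high))


#: Default search spaces for the two classifier families.
SVM_C_SPACE = SearchSpace("box_constraint", 0.1, 10.0, log=True)
KNN_K_SPACE = SearchSpace("k", 1, 30, integer=True)


@dataclass
class BOResult:
    """Trace and incumbent of one Bayesian-optimisation run."""

    trace: list[tuple[float, float]]  # (hyperparameter, objective)
    best_x: float
    best_y: float
    seed: int
    space: SearchSpace

    def incumbent_curve(self) -> np.ndarray:
        """Running maximum of the objective along the trace."""
        return np.maximum.accumulate([y for _, y in self.trace])


def gp_fit(x: np.ndarray, y: np.ndarray):
    """Fit a Matern-5/2 Gaussian process to scalar observations.

    Inputs are expected rescaled to [0, 1]; observation-noise jitter is
    1e-6. Returns ``posterior(x) -> (mu, sigma)``.
    """
    x = np.asarray(x, dtype=np.float64).reshape(-1, 1)
    y = np.asarray(y, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 evaluated points")
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=0.2, length_scale_bounds=(1e-2, 1e2), nu=2.5)
    gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6,
                                  normalize_y=True,
                                  n_restarts_optimizer=0)
    gp.fit(x, y)

    def posterior(xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xq = np.asarray(xq, dtype=np.float64).reshape(-1, 1)
        mu, sigma = gp.predict(xq, return_std=True)
        return mu, sigma

    return posterior


def expected_improvement(mu, sigma, f_best: float):
    """Closed-form expected improvement for a maximised objective.

    EI = (mu - f_best) Phi(z) + sigma phi(z), z = (mu - f_best)/sigma;
    at sigma = 0 it degenerates to max(0, mu - f_best).
    """
    scalar = np.ndim(mu) == 0 and np.ndim(sigma) == 0
    mu = np.atleast_1d(np.asarray(mu, dtype=np.float64))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=np.float64))
    mu, sigma = np.broadcast_arrays(mu, sigma)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    imp = mu - f_best
    ei = np.maximum(imp, 0.0)  # sigma = 0 degenerate case
    pos = sigma > 0
    if np.any(pos):
        z = imp[pos] / sigma[pos]
        ei[pos] = imp[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
    return float(ei[0]) if scalar else ei


def bayes_opt(objective, space: SearchSpace, n_iter: int = 25,
              n_init: int = 5, seed: int = 0,
              n_candidates: int = 1000) -> BOResult:
    """Maximise a 1-D objective by GP + expected improvement.

    ``n_init`` quasi-random (Halton) initial points, then ``n_iter``
    EI-maximising points, EI evaluated on a fresh random candidate grid
    each iteration. Objective failures are logged and skipped.
    Reproducible given *seed*; the incumbent is monotone by
    construction.
    """
    rng = np.random.default_rng(seed)
    halton = qmc.Halton(d=1, seed=seed)
    init_u = halton.random(n_init).ravel()
    trace: list[tuple[float, float]] = []
    obs_u: list[float] = []
    obs_y: list[float] = []

    def evaluate(u: float) -> None:
        xval = space.from_unit(u)
        try:
            yval = float(objective(xval))
        except Exception as exc:
            logger.warning("objective failed at %s=%.4g: %s",
                           space.name, xval, exc)
            return
        trace.append((xval, yval))
        obs_u.append(u)
        obs_y.append(yval)

    for u in init_u:
        evaluate(float(u))
    if not trace:
        raise RuntimeError("every initial objective evaluation failed")

    for _ in range(n_iter):
        candidates = rng.random(n_candidates)
        if len(obs_u) >= 2:
            posterior = gp_fit(np.array(obs_u), np.array(obs_y))
            mu, sigma = posterior(candidates)
            ei = expected_improvement(mu, sigma, max(obs_y))
            u_next = float(candidates[int(np.argmax(ei))])
        else:  # GP needs 2 points; fall back to random
            u_next = float(candidates[0])
        evaluate(u_next)

    best_i = int(np.argmax([y for _, y in trace]))
    return BOResult(trace=trace, best_x=trace[best_i][0],
                    best_y=trace[best_i][1], seed=seed, space=space)


# ---------------------------------------------------------------------------
# Cross-validated objective
# ---------------------------------------------------------------------------

def _train_predict(family: str, hyperparameter: float,
                   X_tr, y_tr, X_te, class_order) -> np.ndarray:
    if family == "svm":
        model = svm_train(X_tr, y_tr, SVMConfig(
            box_constraint=float(hyperparameter), class_order=class_order))
        return svm_predict(model, X_te)[0]
    if family == "knn":
        cfg = KNNConfig(k=int(round(hyperparameter)), class_order=class_order)
        return knn_predict(X_tr, y_tr, X_te, cfg)[0]
    raise ValueError(f"unknown classifier family {family!r}")


def cv_objective(X: np.ndarray, y: np.ndarray, family: str,
                 hyperparameter: float, folds: int = 5, seed: int = 0,
                 class_order: tuple[str, ...] = CLASS_ORDER) -> float:
    """Mean held-out accuracy over stratified folds.

    Fold assignment is deterministic given *seed*; standardisation is
    refit inside each fold (no leakage into the held-out part).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows < {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        stats = standardize_fit(X[tr])
        Z_tr = standardize_apply(X[tr], stats)
        Z_te = standardize_apply(X[te], stats)
        pred = _train_predict(family, hyperparameter, Z_tr, y[tr], Z_te,
                              class_order)
        accs.append(float(np.mean(pred == y[te])))
    return float(np.mean(accs))


def resubstitution_objective(X, y, family, hyperparameter,
                             class_order=CLASS_ORDER) -> float:
    """Training-set accuracy (the optimistic alternative protocol)."""
    stats = standardize_fit(X)
    Z = standardize_apply(X, stats)
    pred = _train_predict(family, hyperparameter, Z, y, Z, class_order)
    return float(np.mean(pred == np.asarray(y)))
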