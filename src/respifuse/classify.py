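"""The SVS (SMOTE - voting - stacking) ensemble classifier.

Training pipeline, all inside the training split only:

1. SMOTE balances the classes by interpolating synthetic minority rows
   between nearest minority neighbors.
2. Each of five base learners (SVM, XGBoost, KNN, logistic regression,
   random forest) is grid-search tuned by inner stratified CV.
3. Each learner receives a decision weight proportional to its inner-CV
   accuracy ("voting").
4. A logistic meta-learner is trained on the out-of-fold base-learner
   probabilities scaled by those weights ("stacking").

Prediction blends the weighted base probabilities through the meta-learner
into a score in [0, 1]; the default operating threshold is the Youden
optimum of the out-of-fold training scores.  Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (GridSearchCV, StratifiedKFold,
                                     cross_val_predict, cross_val_score)
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import ConfigurationError, InputError, SchemaError
from .metrics import MetricsReport, evaluate_predictions, roc_curve
from .records import FeatureTable

BASE_LEARNER_NAMES = ("svm", "xgboost", "knn", "logistic", "random_forest")


def smote_oversample(table: FeatureTable, k: int = 5,
                     seed: int = 0) -> FeatureTable:
    """Balance classes with SMOTE: synthetic minority rows are drawn
    uniformly on segments between a minority row and one of its k nearest
    minority neighbors."""
    y = table.labels
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise InputError("SMOTE requires both classes")
    if counts[0] == counts[1]:
        return table
    minority = int(np.argmin(counts))
    n_new = int(counts.max() - counts.min())
    if counts[minority] <= k:
        raise ConfigurationError(
            f"smote_k={k} must be below the minority count {counts[minority]}")

    rng = np.random.default_rng(seed)
    X = table.values
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, neighbors = nn.kneighbors(Xm)  # column 0 is the point itself

    rows = rng.integers(0, Xm.shape[0], n_new)
    picks = rng.integers(1, k + 1, n_new)
    u = rng.random(n_new)[:, None]
    synthetic = Xm[rows] + u * (Xm[neighbors[rows, picks]] - Xm[rows])

    syn_frame = pd.DataFrame(synthetic, columns=table.feature_names,
                             index=[f"SYN{i:04d}" for i in range(n_new)])
    frame = pd.concat([table.frame, syn_frame])
    labels = np.concatenate([y, np.full(n_new, minority)])
    return FeatureTable(frame, labels)


def _default_learners(seed: int, fast: bool) -> dict[str, tuple[object, dict]]:
    """(estimator, parameter grid) per base learner; grids stay small."""
    trees = 60 if fast else 100
    learners = {
        # sigmoid calibration supplies SVC probabilities
        "svm": (Pipeline([("scale", StandardScaler()),
                          ("clf", CalibratedClassifierCV(
                              SVC(random_state=seed), method="sigmoid", cv=3))]),
                {} if fast else {"clf__estimator__C": [0.1, 1.0, 10.0]}),
        "xgboost": (XGBClassifier(n_estimators=trees, max_depth=3,
                                  learning_rate=0.1, random_state=seed,
                                  n_jobs=1, verbosity=0, eval_metric="logloss"),
                    {} if fast else {"max_depth": [2, 4],
                                     "learning_rate": [0.1, 0.3]}),
        "knn": (Pipeline([("scale", StandardScaler()),
                          ("clf", KNeighborsClassifier())]),
                {} if fast else {"clf__n_neighbors": [3, 5, 7]}),
        "logistic": (Pipeline([("scale", StandardScaler()),
                               ("clf", LogisticRegression(max_iter=2000,
                                                          random_state=seed))]),
                     {} if fast else {"clf__C": [0.1, 1.0, 10.0]}),
        "random_forest": (RandomForestClassifier(n_estimators=trees,
                                                 random_state=seed, n_jobs=1),
                          {} if fast else {"max_depth": [None, 6]}),
    }
    return learners


@dataclass(frozen=True)
class SvsConfig:
    """SVS ensemble configuration.

    ``tuner`` selects the hyperparameter search strategy; ``grid`` is the
    default exhaustive search.  ``fast=True`` collapses every grid to its
    default configuration (used for large replicate benchmarks).
    """

    base_learner_names: tuple[str, ...] = BASE_LEARNER_NAMES
    meta_learner: str = "logistic"
    smote_k: int = 5
    cv_folds: int = 5
    inner_folds: int = 3
    tuner: str = "grid"
    seed: int = 0
    fast: bool = False

    def __post_init__(self) -> None:
        if len(self.base_learner_names) < 2:
            raise ConfigurationError("need at least two base learners")
        unknown = set(self.base_learner_names) - set(BASE_LEARNER_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown base learners: {sorted(unknown)}")
        if self.cv_folds < 2 or self.inner_folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.smote_k < 1:
            raise ConfigurationError("smote_k must be >= 1")
        if self.tuner not in ("grid",):
            raise ConfigurationError(
                f"unknown tuner {self.tuner!r} (pluggable; 'grid' built in)")


@dataclass
class ModelBundle:
    """Fitted base learners, their accuracy weights, the meta-learner and
    the training metadata needed to reproduce the fit."""

    learners: dict[str, object]
    weights: dict[str, float]
    cv_accuracy: dict[str, float]
    meta: object
    threshold: float
    feature_names: list[str]
    config: SvsConfig
    oof_scores: np.ndarray
    oof_labels: np.ndarray


class SVSClassifier:
    """sklearn-style wrapper exposing fit / predict_scores / predict."""

    def __init__(self, config: SvsConfig | None = None):
        self.config = config or SvsConfig()
        self.bundle_: ModelBundle | None = None

    # -- fitting -----------------------------------------------------------
    def fit(self, table: FeatureTable) -> "SVSClassifier":
        cfg = self.config
        y0 = table.labels
        if min(np.bincount(y0, minlength=2)) < cfg.cv_folds:
            raise InputError("need >= cv_folds subjects per class")
        balanced = smote_oversample(table, cfg.smote_k, cfg.seed)
        X, y = balanced.values, balanced.labels

        inner = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True,
                                random_state=cfg.seed)
        defs = _default_learners(cfg.seed, cfg.fast)
        learners: dict[str, object] = {}
        accuracy: dict[str, float] = {}
        oof_probs = np.zeros((X.shape[0], len(cfg.base_learner_names)))
        for j, name in enumerate(cfg.base_learner_names):
            est, grid = defs[name]
            if grid:
                search = GridSearchCV(est, grid, cv=inner, scoring="accuracy",
                                      n_jobs=1)
                search.fit(X, y)
                best = search.best_estimator_
                accuracy[name] = float(search.best_score_)
            else:
                best = clone(est).fit(X, y)
                accuracy[name] = float(np.mean(
                    cross_val_score(clone(est), X, y, cv=inner,
                                    scoring="accuracy")))
            learners[name] = best
            oof_probs[:, j] = cross_val_predict(clone(best), X, y, cv=inner,
                                                method="predict_proba")[:, 1]

        total = sum(accuracy.values())
        weights = {n: a / total for n, a in accuracy.items()}
        w = np.array([weights[n] for n in cfg.base_learner_names])

        meta = LogisticRegression(max_iter=2000, random_state=cfg.seed)
        meta.fit(oof_probs * w, y)
        oof_scores = meta.predict_proba(oof_probs * w)[:, 1]
        threshold = roc_curve(y, oof_scores).threshold

        self.bundle_ = ModelBundle(learners, weights, accuracy, meta,
                                   float(threshold), table.feature_names,
                                   cfg, oof_scores, y)
        return self

    # -- prediction --------------------------------------------------------
    def predict_scores(self, table: FeatureTable) -> np.ndarray:
        bundle = self._require_fit()
        missing = [c for c in bundle.feature_names
                   if c not in table.feature_names]
        if missing:
            raise SchemaError(f"missing feature columns: {missing}")
        X = table.select(bundle.feature_names).values
        names = bundle.config.base_learner_names
        probs = np.column_stack([bundle.learners[n].predict_proba(X)[:, 1]
                                 for n in names])
        w = np.array([bundle.weights[n] for n in names])
        return bundle.meta.predict_proba(probs * w)[:, 1]

    def predict(self, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
        bundle = self._require_fit()
        scores = self.predict_scores(table)
        return (scores >= bundle.threshold).astype(int), scores

    def _require_fit(self) -> ModelBundle:
        if self.bundle_ is None:
            raise RuntimeError("SVSClassifier is not fitted")
        return self.bundle_


@dataclass
class CvResult:
    pooled: MetricsReport
    per_fold: list[MetricsReport]
    scores: np.ndarray
    labels: np.ndarray
    fold_of: np.ndarray


def cross_validate_svs(table: FeatureTable, config: SvsConfig | None = None,
                       feature_builder=None) -> CvResult:
    """Outer stratified CV of the SVS ensemble.

    SMOTE and all tuning happen inside each training split.  If
    ``feature_builder`` is given it is called as
    ``feature_builder(train_table, test_table) -> (train, test)`` per fold,
    so label-using feature construction (e.g. LMF) also stays inside the
    split.  Returns pooled out-of-fold metrics plus per-fold reports.
    """
    cfg = config or SvsConfig()
    y = table.labels
    outer = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                            random_state=cfg.seed)
    scores = np.zeros(len(y), dtype=float)
    fold_of = np.zeros(len(y), dtype=int)
    per_fold: list[MetricsReport] = []
    for fold, (tr, te) in enumerate(outer.split(table.values, y)):
        train, test = table.subset_rows(tr), table.subset_rows(te)
        if feature_builder is not None:
            train, test = feature_builder(train, test)
        clf = SVSClassifier(cfg).fit(train)
        s = clf.predict_scores(test)
        scores[te] = s
        fold_of[te] = fold
        per_fold.append(evaluate_predictions(y[te], s,
                                             clf.bundle_.threshold))
    pooled = roc_curve(y, scores)
    return CvResult(pooled, per_fold, scores, y, fold_of)


def cross_validate_single(table: FeatureTable, learner_name: str,
                          config: SvsConfig | None = None) -> CvResult:
    """Outer CV of one base learner alone (SMOTE still inside the split);
    the comparison baseline for ensemble-dominance checks."""
    cfg = config or SvsConfig()
    defs = _default_learners(cfg.seed, cfg.fast)
    est, _ = defs[learner_name]
    y = table.labels
    outer = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                            random_state=cfg.seed)
    scores = np.zeros(len(y), dtype=float)
    per_fold: list[MetricsReport] = []
    for tr, te in outer.split(table.values, y):
        train = smote_oversample(table.subset_rows(tr), cfg.smote_k, cfg.seed)
        model = clone(est).fit(train.values, train.labels)
        s = model.predict_proba(table.subset_rows(te).values)[:, 1]
        scores[te] = s
        per_fold.append(evaluate_predictions(y[te], s, 0.5))
    pooled = roc_curve(y, scores)
    return CvResult(pooled, per_fold, scores, y, np.zeros(len(y), int))
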