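"""Ensemble-of-balanced-subdatasets training inside stratified k-fold CV.

The cohort is split with stratified 10-fold cross-validation, so every test
fold keeps the cohort's class distribution (test folds are never balanced —
which is also why precision is low at ~8% prevalence). Within each training
fold, the majority class is partitioned across ceil(majority/minority)
balanced subdatasets: each holds every minority subject plus a disjoint,
randomly drawn majority chunk; the last chunk holds the remainder, so no
subject is discarded and none is used twice. One classifier is trained per
subdataset and the member scores are averaged into the ensemble score.

Classifiers: KNN (k=5, vote fraction), LDA (posterior), linear SVM (C=1 with
Platt-calibrated scores), all on features standardized with training-fold
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASSIFIERS = ("KNN", "LDA", "SVM")
DEFAULT_K_FOLDS = 10
DECISION_THRESHOLD = 0.5
#: common FPR grid for vertical ROC averaging across folds
ROC_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class FoldPlan:
    """Stratified fold assignment per subject."""

    k: int
    assignments: np.ndarray  # fold id per subject
    stratified: bool = True

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass
class BalancedSubdataset:
    """All minority subjects plus a disjoint majority chunk."""

    minority: np.ndarray
    majority: np.ndarray

    @property
    def indices(self) -> np.ndarray:
        return np.sort(np.concatenate([self.minority, self.majority]))


@dataclass
class FoldResult:
    """Per-fold ensemble test scores and derived metrics."""

    fold: int
    scores: np.ndarray
    y_true: np.ndarray
    threshold: float = DECISION_THRESHOLD
    tp: int = field(init=False)
    fp: int = field(init=False)
    tn: int = field(init=False)
    fn: int = field(init=False)
    auc: float = field(init=False)
    roc_tpr_on_grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pred = (self.scores >= self.threshold).astype(int)
        y = self.y_true
        self.tp = int(np.sum((pred == 1) & (y == 1)))
        self.fp = int(np.sum((pred == 1) & (y == 0)))
        self.tn = int(np.sum((pred == 0) & (y == 0)))
        self.fn = int(np.sum((pred == 0) & (y == 1)))
        if len(np.unique(y)) < 2:
            self.auc = np.nan
            self.roc_tpr_on_grid = np.full_like(ROC_GRID, np.nan)
        else:
            self.auc = float(roc_auc_score(y, self.scores))
            fpr, tpr, _ = roc_curve(y, self.scores)
            f = interpolate.interp1d(fpr, tpr, kind="previous", bounds_error=False,
                                     fill_value=(0.0, 1.0))
            self.roc_tpr_on_grid = f(ROC_GRID)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else np.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / len(self.y_true)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else np.nan


@dataclass
class ExperimentReport:
    """Fold-averaged metrics of one classifier/feature-set combination."""

    classifier: str
    features: list[str]
    folds: list[FoldResult]
    selection_mode: str = "per-fold"

    def _mean(self, attr: str) -> float:
        vals = [getattr(f, attr) for f in self.folds]
        return float(np.nanmean(vals))

    @property
    def accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def specificity(self) -> float:
        return self._mean("specificity")

    @property
    def sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def precision(self) -> float:
        return self._mean("precision")

    @property
    def auc(self) -> float:
        aucs = [f.auc for f in self.folds if np.isfinite(f.auc)]
        if len(aucs) < len(self.folds):
            warnings.warn("folds with a single test class excluded from the AUC average")
        return float(np.mean(aucs))

    def mean_roc(self) -> tuple[np.ndarray, np.ndarray]:
        tprs = np.vstack([f.roc_tpr_on_grid for f in self.folds if np.isfinite(f.auc)])
        return ROC_GRID, tprs.mean(axis=0)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "accuracy": self.accuracy,
                "specificity": self.specificity,
                "sensitivity": self.sensitivity,
                "precision": self.precision,
                "auc": self.auc,
            },
            name=self.classifier,
        )


def make_folds(y: np.ndarray, k: int = DEFAULT_K_FOLDS, seed: int = 0) -> FoldPlan:
    """Stratified partition into k folds."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > len(y):
        raise ValueError("k exceeds the number of subjects")
    if min(np.bincount(y, minlength=2)) < k:
        warnings.warn("a class has fewer members than folds; some folds lack it")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments)


def balanced_subdatasets(
    train_idx: np.ndarray, y: np.ndarray, seed: int = 0
) -> list[BalancedSubdataset]:
    """Partition the training fold's majority class across balanced subdatasets.

    Produces ceil(majority/minority) subdatasets; the last one holds the
    remainder (slightly imbalanced). Every majority subject is used exactly
    once; every minority subject appears in all subdatasets.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    y_tr = np.asarray(y, dtype=int)[train_idx]
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training fold must contain both classes")
    classes, counts = np.unique(y_tr, return_counts=True)
    minority_cls = classes[np.argmin(counts)]
    minority = train_idx[y_tr == minority_cls]
    majority = train_idx[y_tr != minority_cls]
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(majority)
    m = len(minority)
    return [
        BalancedSubdataset(minority=minority, majority=shuffled[i : i + m])
        for i in range(0, len(shuffled), m)
    ]


def train_classifier(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0, **params):
    """Fit one classifier; returns an object with a score(X) -> P(died) method.

    Features are standardized with the training statistics inside the model
    pipeline. KNN scores are neighbor-vote fractions, LDA scores posteriors,
    SVM scores Platt-calibrated margins.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2 or len(y) < 4:
        raise ValueError("degenerate training set")
    if kind == "KNN":
        k = min(params.get("n_neighbors", 5), len(y))
        model = make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=k))
    elif kind == "LDA":
        model = make_pipeline(
            StandardScaler(), LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        )
    elif kind == "SVM":
        model = make_pipeline(
            StandardScaler(),
            SVC(kernel="linear", C=params.get("C", 1.0), probability=True,
                random_state=seed),
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    model.fit(X, y)

    class _Scorer:
        def __init__(self, m):
            self._m = m
            self.classes_ = m.classes_

        def score(self, Xt: np.ndarray) -> np.ndarray:
            proba = self._m.predict_proba(np.asarray(Xt, dtype=float))
            return proba[:, list(self.classes_).index(1)]

    return _Scorer(model)


def ensemble_predict(scorers: list, X_test: np.ndarray) -> np.ndarray:
    """Unweighted mean of the member scores."""
    if not scorers:
        raise ValueError("need at least one trained member")
    return np.mean([s.score(X_test) for s in scorers], axis=0)


def evaluate(scores: np.ndarray, y_test: np.ndarray, fold: int = 0,
             threshold: float = DECISION_THRESHOLD) -> FoldResult:
    return FoldResult(fold=fold, scores=np.asarray(scores, dtype=float),
                      y_true=np.asarray(y_test, dtype=int), threshold=threshold)


def aggregate(folds: list[FoldResult], classifier: str, features: list[str],
              selection_mode: str = "per-fold") -> ExperimentReport:
    return ExperimentReport(classifier=classifier, features=features, folds=folds,
                            selection_mode=selection_mode)


def run_cv_experiment(
    X: pd.DataFrame,
    y: np.ndarray,
    classifier: str = "LDA",
    k: int = DEFAULT_K_FOLDS,
    seed: int = 0,
    selector=None,
    extra_features: pd.DataFrame | None = None,
) -> ExperimentReport:
    """Full cross-validated ensemble experiment.

    ``selector(X_train, y_train, seed)`` (optional) returns the feature names
    to use, re-run inside every training fold so selection never sees the
    test subjects. ``extra_features`` columns (e.g. clinical covariates) are
    appended to the selected set.
    """
    y = np.asarray(y, dtype=int)
    plan = make_folds(y, k=k, seed=seed)
    folds = []
    used_features: list[str] = list(X.columns)
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        if selector is not None:
            selected = selector(X.iloc[tr], y[tr], seed + 1000 * (fold + 1))
        else:
            selected = list(X.columns)
        Xf = X[selected]
        if extra_features is not None:
            Xf = pd.concat([Xf, extra_features], axis=1)
        used_features = list(Xf.columns)
        subsets = balanced_subdatasets(tr, y, seed=seed + fold)
        Xv = Xf.to_numpy(dtype=float)
        scorers = [
            train_classifier(classifier, Xv[s.indices], y[s.indices], seed=seed)
            for s in subsets
        ]
        scores = ensemble_predict(scorers, Xv[te])
        folds.append(evaluate(scores, y[te], fold=fold))
    return aggregate(folds, classifier, used_features,
                     selection_mode="per-fold" if selector else "fixed")
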