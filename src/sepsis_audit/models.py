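"""Mortality-prediction harness: 7:3 split, 0-1 scaling, 16 tuned classifiers.

The sixteen model configurations predict in-hospital death from three features
(first-24 h SOFA, first-24 h SIRS, age) min-max scaled to [0,1] on the
training data. Hyperparameters are tuned by 5-fold cross-validated AUC over a
small default grid per configuration, the winning configuration is refit on
the full training set, and a decision threshold is chosen on the training
scores by Youden's J. Models without probabilistic outputs contribute their
signed decision scores; AUC needs only a ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import (
    LogisticRegression,
    Perceptron,
    RidgeClassifier,
    SGDClassifier,
)
from sklearn.model_selection import GridSearchCV, ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import BernoulliNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, MinMaxScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.utils.validation import check_is_fitted, check_X_y

from ._seeds import derive_seed

FEATURES = ("sofa_24h", "sirs_24h", "age")
OUTCOME = "in_hospital_death"

METRIC_COLUMNS = (
    "Accuracy",
    "AUC",
    "Precision",
    "Recall",
    "F1_binary",
    "F1_macro",
    "Specificity",
)


# ---------------------------------------------------------------------------
# split and scaling
# ---------------------------------------------------------------------------

def split_cohort(
    patients: pd.DataFrame, train_fraction: float = 0.7, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random (unstratified) disjoint, exhaustive 7:3-style partition.

    ``|train| = round(train_fraction * n)`` with half-up rounding; both parts
    must be non-empty.
    """
    n = len(patients)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    if n_train < 1 or n_train >= n:
        raise ValueError(
            f"train_fraction={train_fraction} leaves an empty partition for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return patients.iloc[train_idx], patients.iloc[test_idx]


@dataclass(frozen=True)
class ScalingBounds:
    columns: tuple[str, ...]
    minimum: np.ndarray
    maximum: np.ndarray


def fit_scaler(train: pd.DataFrame, columns: Sequence[str] = FEATURES) -> ScalingBounds:
    """Learn per-column min-max bounds from training rows only.

    A constant column cannot be mapped onto [0,1] and is rejected by name.
    """
    if len(train) == 0:
        raise ValueError("cannot fit scaler on an empty training set")
    X = train[list(columns)].to_numpy(dtype=float)
    scaler = MinMaxScaler().fit(X)
    for j, col in enumerate(columns):
        if scaler.data_max_[j] <= scaler.data_min_[j]:
            raise ValueError(f"column {col!r} is constant in the training data")
    return ScalingBounds(tuple(columns), scaler.data_min_.copy(), scaler.data_max_.copy())


def apply_scaler(bounds: ScalingBounds, rows: pd.DataFrame) -> np.ndarray:
    """Affine map using training bounds; values outside them pass through
    (test rows may land outside [0,1])."""
    X = rows[list(bounds.columns)].to_numpy(dtype=float)
    return (X - bounds.minimum) / (bounds.maximum - bounds.minimum)


def inverse_scaler(bounds: ScalingBounds, scaled: np.ndarray) -> np.ndarray:
    return scaled * (bounds.maximum - bounds.minimum) + bounds.minimum


# ---------------------------------------------------------------------------
# AUC and Youden threshold
# ---------------------------------------------------------------------------

def auc(scores: Sequence, labels: Sequence) -> float:
    """Rank-based (Mann-Whitney) AUC: probability a random positive outscores
    a random negative, ties counted 1/2.

    Returns NaN — the "undefined" signal, not an error — when only one class
    is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def youden_threshold(scores: Sequence, labels: Sequence) -> float:
    """Candidate threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent sorted unique scores plus
    -inf/+inf sentinels; prediction is positive at ``score >= threshold``.
    Ties in J resolve to the lowest candidate.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("youden_threshold requires both outcome classes")
    u = np.unique(s)
    candidates = np.concatenate(([-np.inf], (u[:-1] + u[1:]) / 2.0, [np.inf]))
    # counts of scores >= t via sorted per-class score arrays
    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    tp = n1 - np.searchsorted(pos_sorted, candidates, side="left")
    fp = n0 - np.searchsorted(neg_sorted, candidates, side="left")
    tn = n0 - fp
    # J = tp/n1 + tn/n0 - 1; maximize the equivalent integer score so exact
    # ties resolve to the lowest candidate without float jitter
    j_scaled = tp * n0 + tn * n1
    return float(candidates[int(np.argmax(j_scaled))])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    auc: float
    precision: float
    recall: float
    f1_binary: float
    f1_macro: float
    specificity: float
    precision_undefined: bool = False

    def as_row(self) -> dict[str, float]:
        return {
            "Accuracy": self.accuracy,
            "AUC": self.auc,
            "Precision": self.precision,
            "Recall": self.recall,
            "F1_binary": self.f1_binary,
            "F1_macro": self.f1_macro,
            "Specificity": self.specificity,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(scores: Sequence, threshold: float, labels: Sequence) -> MetricSet:
    """Confusion-matrix metric suite at ``score >= threshold`` -> positive.

    Precision with no predicted positives is reported as 0 with the
    ``precision_undefined`` flag set; F1_macro is the unweighted mean of the
    per-class F1 scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pred = s >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    n = tp + fp + fn + tn
    precision_undefined = (tp + fp) == 0
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1_pos = _safe_div(2 * precision * recall, precision + recall)
    prec_neg = _safe_div(tn, tn + fn)
    rec_neg = specificity
    f1_neg = _safe_div(2 * prec_neg * rec_neg, prec_neg + rec_neg)
    if precision_undefined:
        warnings.warn("no predicted positives: precision reported as 0", stacklevel=2)
    return MetricSet(
        accuracy=_safe_div(tp + tn, n),
        auc=auc(s, y),
        precision=precision,
        recall=recall,
        f1_binary=f1_pos,
        f1_macro=(f1_pos + f1_neg) / 2.0,
        specificity=specificity,
        precision_undefined=precision_undefined,
    )


# ---------------------------------------------------------------------------
# the sixteen model configurations
# ---------------------------------------------------------------------------

_C_GRID = [0.01, 0.1, 1.0, 10.0]
_ALPHA_GRID = [1e-4, 1e-3, 1e-2, 1e-1]
_SVC_C_GRID = [0.1, 1.0, 10.0, 100.0]

MODEL_NAMES = (
    "Ridge classifier",
    "Perceptron",
    "Passive-aggressive",
    "kNN",
    "Random forest",
    "LinearSVC_L1",
    "LinearSVC_L2",
    "SGDClassifier_L1",
    "SGDClassifier_L2",
    "SGDClassifier_EN",
    "MultinomialNB",
    "BernoulliNB",
    "Logistic regression",
    "SVC_rbf",
    "SVC_poly",
    "SVC_sigmoid",
)


@dataclass
class ModelSpec:
    """One named configuration: a base estimator plus its tuning grid."""

    name: str
    estimator: BaseEstimator
    hyperparameter_grid: Mapping[str, list] = field(default_factory=dict)
    cv_folds: int = 5
    seed: int | None = None


def _clip_nonneg() -> FunctionTransformer:
    # multinomial NB requires non-negative inputs; scaled test rows can dip
    # below 0 when a test value undercuts the training minimum
    return FunctionTransformer(np.clip, kw_args={"a_min": 0.0, "a_max": None})


def default_model_specs(seed: int = 0, cv_folds: int = 5) -> list[ModelSpec]:
    """The sixteen configurations with small default grids, all overridable."""

    def rs(name: str) -> int:
        return derive_seed(seed, "model", name)

    raw: list[tuple[str, BaseEstimator, Mapping[str, list]]] = [
        ("Ridge classifier", RidgeClassifier(), {"alpha": [0.01, 0.1, 1.0, 10.0]}),
        (
            "Perceptron",
            Perceptron(penalty="l2", max_iter=1000, random_state=rs("Perceptron")),
            {"alpha": _ALPHA_GRID},
        ),
        (
            # passive-aggressive classifier, in its SGD formulation
            # (hinge loss, no penalty, PA-I learning rate; eta0 is the
            # aggressiveness parameter C)
            "Passive-aggressive",
            SGDClassifier(
                loss="hinge", penalty=None, learning_rate="pa1", eta0=1.0,
                max_iter=1000, random_state=rs("Passive-aggressive"),
            ),
            {"eta0": _C_GRID},
        ),
        ("kNN", KNeighborsClassifier(), {"n_neighbors": [3, 5, 11, 21]}),
        (
            "Random forest",
            RandomForestClassifier(random_state=rs("Random forest")),
            {"n_estimators": [100, 300], "max_depth": [None, 5]},
        ),
        (
            "LinearSVC_L1",
            LinearSVC(penalty="l1", dual=False, max_iter=5000,
                      random_state=rs("LinearSVC_L1")),
            {"C": _C_GRID},
        ),
        (
            # dual liblinear draws coordinates at random: seed it for
            # run-to-run reproducibility
            "LinearSVC_L2",
            LinearSVC(penalty="l2", dual=True, max_iter=5000,
                      random_state=rs("LinearSVC_L2")),
            {"C": _C_GRID},
        ),
        (
            "SGDClassifier_L1",
            SGDClassifier(penalty="l1", max_iter=1000, random_state=rs("SGDClassifier_L1")),
            {"alpha": _ALPHA_GRID},
        ),
        (
            "SGDClassifier_L2",
            SGDClassifier(penalty="l2", max_iter=1000, random_state=rs("SGDClassifier_L2")),
            {"alpha": _ALPHA_GRID},
        ),
        (
            "SGDClassifier_EN",
            SGDClassifier(
                penalty="elasticnet", l1_ratio=0.15, max_iter=1000,
                random_state=rs("SGDClassifier_EN"),
            ),
            {"alpha": _ALPHA_GRID},
        ),
        (
            "MultinomialNB",
            Pipeline([("clip", _clip_nonneg()), ("nb", MultinomialNB())]),
            {"nb__alpha": [0.01, 0.1, 1.0, 10.0]},
        ),
        # BernoulliNB binarizes the scaled features at 0.5
        ("BernoulliNB", BernoulliNB(binarize=0.5), {"alpha": [0.01, 0.1, 1.0, 10.0]}),
        ("Logistic regression", LogisticRegression(max_iter=1000), {"C": _C_GRID}),
        # libsvm iteration cap bounds the kernel solvers at large C without
        # materially changing the fitted scores
        ("SVC_rbf", SVC(kernel="rbf", max_iter=100_000), {"C": _SVC_C_GRID}),
        ("SVC_poly", SVC(kernel="poly", max_iter=100_000), {"C": _SVC_C_GRID}),
        ("SVC_sigmoid", SVC(kernel="sigmoid", max_iter=100_000), {"C": _SVC_C_GRID}),
    ]
    return [
        ModelSpec(name=name, estimator=est, hyperparameter_grid=grid,
                  cv_folds=cv_folds, seed=derive_seed(seed, "cv", name))
        for name, est, grid in raw
    ]


def _decision_scores(estimator: BaseEstimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X), dtype=float)
    proba = estimator.predict_proba(X)
    return np.asarray(proba[:, -1], dtype=float)


class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Risk-score classifier with CV-tuned hyperparameters and a Youden cut.

    Wraps any sklearn classifier exposing ``decision_function`` or
    ``predict_proba``. ``fit`` tunes the wrapped estimator's hyperparameters by
    mean 5-fold cross-validated AUC over ``param_grid`` (ties resolve to the
    first grid point in ``ParameterGrid`` order), refits the winner on the full
    training data, and sets ``threshold_`` to the Youden-J-optimal cut of the
    training scores. ``decision_function`` returns the risk score (higher =
    higher predicted mortality); ``predict`` applies ``threshold_``.
    """

    def __init__(self, estimator=None, param_grid=None, cv=5, random_state=None):
        self.estimator = estimator
        self.param_grid = param_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("both outcome classes must be present in training data")
        base = clone(self.estimator) if self.estimator is not None else LogisticRegression(
            max_iter=1000
        )
        grid = dict(self.param_grid or {})
        candidates = list(ParameterGrid(grid)) if grid else [{}]
        if len(candidates) > 1:
            folds = StratifiedKFold(
                n_splits=self.cv, shuffle=True, random_state=self.random_state
            )
            search = GridSearchCV(
                base, grid, scoring="roc_auc", cv=folds, refit=True, n_jobs=None,
                error_score="raise",
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                search.fit(X, y)
            self.best_estimator_ = search.best_estimator_
            self.best_params_ = search.best_params_
            self.cv_results_ = search.cv_results_
        else:
            if candidates[0]:
                base.set_params(**candidates[0])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                base.fit(X, y)
            self.best_estimator_ = base
            self.best_params_ = candidates[0]
            self.cv_results_ = None
        train_scores = _decision_scores(self.best_estimator_, X)
        self.threshold_ = youden_threshold(train_scores, y == self.classes_[1])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "best_estimator_")
        return _decision_scores(self.best_estimator_, np.asarray(X, dtype=float))

    def predict(self, X):
        scores = self.decision_function(X)
        return np.where(scores >= self.threshold_, self.classes_[1], self.classes_[0])


@dataclass
class FittedClassifier:
    """A tuned configuration: deterministic score function plus its threshold."""

    spec: ModelSpec
    model: YoudenThresholdClassifier
    threshold: float
    chosen_hyperparameters: dict

    def score_rows(self, X: np.ndarray) -> np.ndarray:
        return self.model.decision_function(X)


def tune_and_fit(spec: ModelSpec, X: np.ndarray, y: Sequence) -> FittedClassifier:
    """Tune, refit and threshold one configuration on the training matrix."""
    ytc = YoudenThresholdClassifier(
        estimator=spec.estimator,
        param_grid=dict(spec.hyperparameter_grid),
        cv=spec.cv_folds,
        random_state=spec.seed,
    )
    ytc.fit(X, np.asarray(y).astype(int))
    return FittedClassifier(
        spec=spec,
        model=ytc,
        threshold=float(ytc.threshold_),
        chosen_hyperparameters=dict(ytc.best_params_),
    )


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

def run_model_battery(
    train: pd.DataFrame,
    test: pd.DataFrame,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 0,
    determinants: Sequence[str] = ("race", "sex", "marital", "insurance", "language"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every configuration and evaluate it on the held-out test set.

    Returns ``(metrics, scores)``: a per-model metric table with the standard
    metric columns, and a long per-patient score table (patient_id, model,
    score, label, plus the determinant columns) consumed by the disparity
    tests.
    """
    if specs is None:
        specs = default_model_specs(seed=seed)
    bounds = fit_scaler(train)
    X_train = apply_scaler(bounds, train)
    X_test = apply_scaler(bounds, test)
    y_train = train[OUTCOME].to_numpy(dtype=int)
    y_test = test[OUTCOME].to_numpy(dtype=int)
    metric_rows = []
    score_frames = []
    for spec in specs:
        fitted = tune_and_fit(spec, X_train, y_train)
        test_scores = fitted.score_rows(X_test)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ms = compute_metrics(test_scores, fitted.threshold, y_test)
        metric_rows.append({"model": spec.name, **ms.as_row()})
        frame = pd.DataFrame(
            {
                "patient_id": test["patient_id"].to_numpy(),
                "model": spec.name,
                "score": test_scores,
                "label": y_test,
            }
        )
        for det in determinants:
            frame[det] = test[det].to_numpy()
        score_frames.append(frame)
    metrics = pd.DataFrame(metric_rows, columns=["model", *METRIC_COLUMNS])
    scores = pd.concat(score_frames, ignore_index=True)
    return metrics, scores
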