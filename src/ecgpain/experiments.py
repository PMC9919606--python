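"""Train/test designs, the eight-classifier roster and six evaluation metrics.

Three designs are realized over the labeled feature table:

* ``dependent`` — 5 repetitions of stratified 2-fold cross-validation (10
  evaluations); rows from the same participant-session may appear on both
  sides, never the same row.
* ``session_independent`` — train on all session-1 rows, test on all
  session-2 rows (one evaluation).
* ``participant_independent`` — leave-one-participant-out: per held-out
  participant, train on session-1 rows of everyone else and test on the
  held-out participant's session-2 rows.

Classifiers are configured with their library defaults (the roster's
reference configuration); metrics are computed from the confusion counts by
their closed-form definitions, with zero-denominator ratios returned as 0
and flagged.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ecgpain.features import FEATURE_COLUMNS

log = logging.getLogger(__name__)

#: The eight classifier families, in canonical order.
ROSTER = (
    "adaboost", "decision_tree", "knn", "lda",
    "logistic", "random_forest", "svm_linear", "svm_rbf",
)

APPROACHES = ("dependent", "session_independent", "participant_independent")


class DesignError(ValueError):
    """The requested split cannot be built on this table."""


class TrainingError(ValueError):
    """Training preconditions violated (e.g. a single-class training set)."""


@dataclass(frozen=True)
class ClassifierSpec:
    """A roster family with its reference hyperparameters and a seed."""

    family: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ROSTER:
            raise ValueError(f"unknown family {self.family!r}; roster = {ROSTER}")

    def build(self, n_train: int | None = None):
        """Instantiate the scikit-learn estimator with default parameters."""
        fam = self.family
        if fam == "adaboost":
            return AdaBoostClassifier(n_estimators=50, learning_rate=1.0,
                                      random_state=self.seed, **self.params)
        if fam == "decision_tree":
            return DecisionTreeClassifier(criterion="gini", splitter="best",
                                          random_state=self.seed, **self.params)
        if fam == "knn":
            k = self.params.get("n_neighbors", 5)
            if n_train is not None:
                # cap k at the training-set size so degenerate sets still fit
                k = min(k, n_train)
            return KNeighborsClassifier(n_neighbors=k, metric="minkowski", p=2)
        if fam == "lda":
            return LinearDiscriminantAnalysis(solver="svd", **self.params)
        if fam == "logistic":
            return LogisticRegression(C=1.0, solver="lbfgs",
                                      max_iter=100, **self.params)
        if fam == "random_forest":
            return RandomForestClassifier(n_estimators=100, criterion="gini",
                                          max_features="sqrt", bootstrap=True,
                                          random_state=self.seed, **self.params)
        if fam == "svm_linear":
            return SVC(kernel="linear", C=1.0, gamma="scale",
                       random_state=self.seed, **self.params)
        if fam == "svm_rbf":
            return SVC(kernel="rbf", C=1.0, gamma="scale",
                       random_state=self.seed, **self.params)
        raise ValueError(fam)


@dataclass
class SplitPlan:
    """Ordered (train positions, test positions) pairs into a feature table."""

    approach: str
    evaluations: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    @property
    def n_evaluations(self) -> int:
        return len(self.evaluations)


def build_split(approach: str, table: pd.DataFrame, seed: int = 0,
                n_repetitions: int = 5, n_folds: int = 2) -> SplitPlan:
    """Build one of the three evaluation designs on a labeled feature table."""
    if approach not in APPROACHES:
        raise DesignError(f"unknown approach {approach!r}")
    if "label" not in table.columns:
        raise DesignError("table must carry a 'label' column")
    y = table["label"].to_numpy(dtype=int)
    positions = np.arange(len(table))
    sessions = table["session"].to_numpy()
    participants = table["participant"].to_numpy()

    evaluations: list[tuple[np.ndarray, np.ndarray]] = []
    if approach == "dependent":
        rng = np.random.default_rng(seed)
        for _ in range(n_repetitions):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                  random_state=rep_seed)
            for train_idx, test_idx in skf.split(positions, y):
                evaluations.append((positions[train_idx], positions[test_idx]))
    elif approach == "session_independent":
        if not ({1, 2} <= set(np.unique(sessions).tolist())):
            raise DesignError("session-independent design needs two sessions")
        train = positions[sessions == 1]
        test = positions[sessions == 2]
        evaluations.append((train, test))
    else:  # participant_independent
        if not ({1, 2} <= set(np.unique(sessions).tolist())):
            raise DesignError("participant-independent design needs two sessions")
        for p in sorted(pd.unique(participants)):
            train = positions[(sessions == 1) & (participants != p)]
            test = positions[(sessions == 2) & (participants == p)]
            if test.size == 0 or train.size == 0:
                continue
            evaluations.append((train, test))

    for idx, (train, test) in enumerate(evaluations):
        assert np.intersect1d(train, test).size == 0
        log.debug("split %s[%d]: %d train / %d test rows (seed %d)",
                  approach, idx, train.size, test.size, seed)
    log.info("split %s: %d evaluations on %d rows (seed %d)",
             approach, len(evaluations), len(table), seed)
    return SplitPlan(approach=approach, evaluations=evaluations, seed=seed)


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    """Fit the specified family on the training rows."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise TrainingError("training set must contain both classes")
    model = spec.build(n_train=len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


@dataclass(frozen=True)
class MetricsReport:
    """Six evaluation metrics plus the underlying confusion counts."""

    accuracy: float
    balanced_accuracy: float
    f1: float
    mcc: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "mcc": self.mcc,
            "precision": self.precision,
            "recall": self.recall,
        }


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Closed-form metrics from the binary confusion matrix.

    Zero-denominator ratios come back as 0 and are listed in ``undefined``.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences must have equal length")
    if y_true.size == 0:
        raise ValueError("label sequences must be non-empty")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")

    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))

    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / (tp + fp + fn + tn)
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    balanced_accuracy = (recall + specificity) / 2.0
    precision = ratio(tp, tp + fp, "precision")
    f1 = ratio(2.0 * precision * recall, precision + recall, "f1")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ratio(tp * tn - fp * fn, mcc_den, "mcc")

    return MetricsReport(
        accuracy=accuracy, balanced_accuracy=balanced_accuracy, f1=f1,
        mcc=mcc, precision=precision, recall=recall,
        tp=tp, fp=fp, fn=fn, tn=tn, undefined=tuple(undefined),
    )


def run_experiment(approach: str, table: pd.DataFrame,
                   roster: tuple[str, ...] = ROSTER,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every roster family on every evaluation of the design.

    Returns ``(summary, detail)``: the summary holds the unweighted mean of
    each metric across evaluations per model, the detail one row per
    (model, evaluation, metric value set).  Failed evaluations are recorded
    and skipped, the rest continue.
    """
    plan = build_split(approach, table, seed=seed)
    X = table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)

    root = np.random.SeedSequence(seed)
    model_seeds = {
        fam: int(np.random.default_rng(seq).integers(0, 2**31 - 1))
        for fam, seq in zip(roster, root.spawn(len(roster)))
    }

    detail_rows = []
    for family in roster:
        spec = ClassifierSpec(family=family, seed=model_seeds[family])
        for ev_idx, (train, test) in enumerate(plan.evaluations):
            try:
                model = train_classifier(spec, X[train], y[train])
                pred = model.predict(X[test])
                report = compute_metrics(y[test], pred)
            except (TrainingError, ValueError) as exc:
                detail_rows.append({
                    "model": family, "approach": approach,
                    "evaluation": ev_idx, "error": str(exc),
                })
                continue
            row = {"model": family, "approach": approach, "evaluation": ev_idx,
                   "n_train": len(train), "n_test": len(test), "error": ""}
            row.update(report.as_dict())
            detail_rows.append(row)

    detail = pd.DataFrame(detail_rows)
    ok = detail[detail["error"] == ""] if "error" in detail else detail
    metric_cols = ["accuracy", "balanced_accuracy", "f1", "mcc",
                   "precision", "recall"]
    summary = (
        ok.groupby("model")[metric_cols].mean().reset_index()
        .assign(approach=approach, n_evaluations=plan.n_evaluations)
    )
    return summary, detail
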