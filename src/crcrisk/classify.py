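"""Classifier benchmark: six validation regimes, confusion metrics, and an
integer back-solver that audits printed aggregate figures.

The bench trains a roster of standard classifiers on the Boolean label matrix
with the thresholded risk label as response, under either pooled k-fold
cross-validation (k in {5, 25, 50}) or a single random holdout split (5%,
15%, 25% held out).  Metrics follow the usual confusion-matrix definitions;
the false-negative percentage is reported relative to the whole dataset for
k-fold and relative to the validation set for holdout.  Printed percentages
in published tables are sometimes truncated rather than rounded, so the
back-solver accepts either convention at the printed precision.
"""
from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .labeling import LabelMatrix

KFOLD = "kfold"
HOLDOUT = "holdout"

DENOM_WHOLE = "whole_dataset"
DENOM_VALIDATION = "validation_set"


class ProtocolError(ValueError):
    """A validation protocol cannot be applied to the given data."""


class InconsistentMetricsError(ValueError):
    """No integer confusion matrix reproduces the printed aggregate figures."""


@dataclass(frozen=True)
class ValidationProtocol:
    """Either k-fold cross validation or a single random holdout split."""

    kind: str
    k: int | None = None
    holdout_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind == KFOLD:
            if self.k is None or self.holdout_fraction is not None:
                raise ProtocolError("kfold protocol takes k only")
            if self.k < 2:
                raise ProtocolError("k must be >= 2")
        elif self.kind == HOLDOUT:
            if self.holdout_fraction is None or self.k is not None:
                raise ProtocolError("holdout protocol takes holdout_fraction only")
            if not (0.0 < self.holdout_fraction < 1.0):
                raise ProtocolError("holdout fraction must lie in (0, 1)")
        else:
            raise ProtocolError(f"unknown protocol kind {self.kind!r}")

    @property
    def name(self) -> str:
        if self.kind == KFOLD:
            return f"kfold{self.k}"
        return f"holdout{round(self.holdout_fraction * 100):g}"


#: The six validation regimes of the benchmark.
STANDARD_PROTOCOLS: tuple[ValidationProtocol, ...] = (
    ValidationProtocol(KFOLD, k=5),
    ValidationProtocol(KFOLD, k=25),
    ValidationProtocol(KFOLD, k=50),
    ValidationProtocol(HOLDOUT, holdout_fraction=0.05),
    ValidationProtocol(HOLDOUT, holdout_fraction=0.15),
    ValidationProtocol(HOLDOUT, holdout_fraction=0.25),
)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Accuracy/sensitivity/specificity/precision (%) plus %FN.

    Ratios whose denominator is empty are ``None`` (undefined), never 0.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    pct_false_negatives: float | None
    denominator: str
    denominator_total: int


def confusion(predictions, truth) -> ConfusionMatrix:
    """2x2 cross-tabulation; positive = 1 = suspected to have cancer."""
    pred = np.asarray(predictions).astype(int)
    y = np.asarray(truth).astype(int)
    if pred.shape != y.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {y.shape}")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (y == 1)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(cm: ConfusionMatrix, denominator_total: int,
            denominator_kind: str = DENOM_WHOLE) -> MetricSet:
    """The four confusion measures x100 plus %FN over the stated denominator."""
    if denominator_total <= 0:
        raise ValueError("denominator_total must be positive")
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
        pct_false_negatives=_ratio(cm.fn, denominator_total),
        denominator=denominator_kind,
        denominator_total=denominator_total,
    )


def _printed_match(value: float, printed: float, decimals: int) -> bool:
    """Does `value` print as `printed` under round-half-up or truncation?

    Matching is exact at the printed precision (any looser tolerance admits
    spurious integer matrices in the back-solver).
    """
    scale = 10 ** decimals
    rounded = math.floor(value * scale + 0.5) / scale
    truncated = math.floor(value * scale) / scale
    return min(abs(rounded - printed), abs(truncated - printed)) <= 1e-9


def _decimals_of(x: float) -> int:
    s = f"{x!r}"
    return len(s.split(".")[1]) if "." in s else 0


def solve_confusion(total: int, accuracy: float, fn: int, precision: float) -> ConfusionMatrix:
    """Recover the unique integer confusion matrix behind printed aggregates.

    Given the dataset (or validation-set) size, the printed accuracy (%), the
    false-negative count and the printed precision (%), enumerate the integer
    matrices consistent with the printed figures at their stated precision
    (accepting both rounding and truncation) and return the unique solution.
    """
    acc_dec = _decimals_of(accuracy)
    prec_dec = _decimals_of(precision)
    solutions: set[ConfusionMatrix] = set()
    for correct in range(0, total + 1):  # correct = tp + tn
        if not _printed_match(100.0 * correct / total, accuracy, acc_dec):
            continue
        fp = total - correct - fn
        if fp < 0:
            continue
        for tp in range(0, correct + 1):
            if tp + fp == 0:
                continue
            if _printed_match(100.0 * tp / (tp + fp), precision, prec_dec):
                solutions.add(ConfusionMatrix(tp=tp, fn=fn, tn=correct - tp, fp=fp))
    if not solutions:
        raise InconsistentMetricsError(
            f"no integer confusion matrix reproduces total={total}, "
            f"accuracy={accuracy}, fn={fn}, precision={precision}"
        )
    if len(solutions) > 1:
        raise InconsistentMetricsError(
            f"printed figures are ambiguous: {sorted(solutions, key=lambda c: c.tp)}"
        )
    return solutions.pop()


def printed_consistency(cm: ConfusionMatrix, printed: dict[str, float],
                        denominator_total: int,
                        denominator_kind: str = DENOM_WHOLE) -> dict[str, bool]:
    """Check which printed figures the matrix reproduces (round or truncate)."""
    m = metrics(cm, denominator_total, denominator_kind)
    report = {}
    for key, value in printed.items():
        computed = getattr(m, key)
        report[key] = computed is not None and _printed_match(
            computed, value, _decimals_of(value))
    return report


def default_roster(seed: int = 0) -> dict[str, object]:
    """The six benchmark classifiers (plus callers may add their own).

    The Gaussian SVM uses kernel scale sqrt(n_features)=sqrt(45), i.e.
    rbf gamma = 1/45, the "medium Gaussian" convention; kNN uses k=10.
    """
    return {
        "logistic_regression": LogisticRegression(max_iter=2000),
        "linear_discriminant": LinearDiscriminantAnalysis(),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "bagged_trees": BaggingClassifier(
            DecisionTreeClassifier(random_state=seed), n_estimators=30,
            random_state=seed),
        "gaussian_svm": SVC(kernel="rbf", gamma=1.0 / 45.0, random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=10),
    }


@dataclass
class BenchRow:
    model: str
    protocol: str
    cm: ConfusionMatrix
    metric_set: MetricSet
    seconds: float
    best: bool = False


@dataclass
class BenchReport:
    rows: list[BenchRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "model": r.model,
                "protocol": r.protocol,
                "accuracy": r.metric_set.accuracy,
                "sensitivity": r.metric_set.sensitivity,
                "specificity": r.metric_set.specificity,
                "precision": r.metric_set.precision,
                "pct_false_negatives": r.metric_set.pct_false_negatives,
                "tp": r.cm.tp, "fn": r.cm.fn, "tn": r.cm.tn, "fp": r.cm.fp,
                "seconds": r.seconds,
                "best": r.best,
            }
            for r in self.rows
        ])


def _features_response(features, response):
    X = features.values if isinstance(features, LabelMatrix) else np.asarray(features)
    y = np.asarray(response).astype(int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and response are not aligned")
    return X.astype(float), y


def run_protocol(features, response, protocol: ValidationProtocol,
                 roster: dict[str, object] | None = None, seed: int = 0,
                 include_majority_baseline: bool = True) -> BenchReport:
    """Run every roster model under one validation protocol.

    k-fold: out-of-fold predictions over all folds are pooled into a single
    confusion matrix per model, and %FN is relative to the whole dataset.
    Holdout: one random (unstratified) split; metrics and %FN are computed on
    the held-out records only.
    """
    X, y = _features_response(features, response)
    n = len(y)
    if roster is None:
        roster = default_roster(seed)
    if not roster:
        raise ValueError("roster must not be empty")
    roster = dict(roster)
    if include_majority_baseline:
        roster.setdefault("majority_baseline", DummyClassifier(strategy="most_frequent"))

    report = BenchReport()
    if protocol.kind == KFOLD:
        if protocol.k > n:
            raise ProtocolError(f"k={protocol.k} exceeds the {n} available records")
        if protocol.k > min(np.bincount(y, minlength=2)[np.bincount(y, minlength=2) > 0]):
            # a class smaller than k would leave folds without that class
            raise ProtocolError(f"k={protocol.k} exceeds the smallest class count")
        splitter = KFold(n_splits=protocol.k, shuffle=True, random_state=seed)
        for name, model in roster.items():
            t0 = time.perf_counter()
            pooled = np.empty(n, dtype=int)
            for train_idx, val_idx in splitter.split(X):
                est = clone(model)
                est.fit(X[train_idx], y[train_idx])
                pooled[val_idx] = est.predict(X[val_idx])
            cm = confusion(pooled, y)
            report.rows.append(BenchRow(
                model=name, protocol=protocol.name, cm=cm,
                metric_set=metrics(cm, n, DENOM_WHOLE),
                seconds=time.perf_counter() - t0))
    else:
        n_val = int(round(protocol.holdout_fraction * n))
        if n_val < 1 or n_val >= n:
            raise ProtocolError(f"holdout fraction {protocol.holdout_fraction} leaves "
                                f"an empty train or validation set for n={n}")
        train_idx, val_idx = train_test_split(
            np.arange(n), test_size=n_val, random_state=seed, shuffle=True)
        for name, model in roster.items():
            t0 = time.perf_counter()
            est = clone(model)
            est.fit(X[train_idx], y[train_idx])
            cm = confusion(est.predict(X[val_idx]), y[val_idx])
            report.rows.append(BenchRow(
                model=name, protocol=protocol.name, cm=cm,
                metric_set=metrics(cm, n_val, DENOM_VALIDATION),
                seconds=time.perf_counter() - t0))

    scored = [r for r in report.rows if r.model != "majority_baseline"]
    if scored:
        best = max(scored, key=lambda r: (r.metric_set.accuracy or 0.0))
        best.best = True
    return report


def run_bench(features, response, protocols=STANDARD_PROTOCOLS,
              roster: dict[str, object] | None = None, seed: int = 0) -> BenchReport:
    """All protocols x all roster models, one pooled report."""
    report = BenchReport()
    for protocol in protocols:
        report.rows.extend(
            run_protocol(features, response, protocol, roster=roster, seed=seed).rows)
    return report
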