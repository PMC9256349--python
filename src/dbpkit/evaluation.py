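"""Normalization, confusion-count metrics, and cross-validation protocol.

The evaluation protocol is: (1) MinMax-normalize every feature of the
training table to [0, 1]; (2) stratified five-fold cross-validation, with
per-fold fit/predict and metrics pooled over the union of held-out
predictions; (3) for an independent test set, fit on the whole (normalized)
training table and score the test predictions with the same metrics.

Metrics from confusion counts::

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

with the conventions that an undefined ratio is reported as 0 and flagged,
and MCC is 0 whenever a factor under the root vanishes.

Note the default protocol normalizes the training table once, *before*
folding — faithful to the comparative protocol it implements, but the
fold-held-out rows then inform the scaling.  Pass ``fold_safe=True`` to
refit the normalizer inside each fold instead.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from .errors import ConfigError
from .features import FeatureTable

CLASSIFIERS = ("gnb", "knn", "dt", "lr", "svm-rbf", "linsvm", "rf",
               "gbdt", "xgb")


def _load_classifier_defaults() -> dict:
    text = (importlib.resources.files("dbpkit") / "data" /
            "classifier_defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS = _load_classifier_defaults()


def make_classifier(descriptor: str | Mapping[str, object], seed: int = 0):
    """Instantiate a roster classifier from its descriptor.

    ``descriptor`` is a roster name or ``{"name": ..., "params": {...}}``;
    parameters default to the pinned configuration file and any stochastic
    estimator receives ``seed``.
    """
    from sklearn.ensemble import (GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    if isinstance(descriptor, str):
        name, overrides = descriptor, {}
    else:
        name = str(descriptor["name"])
        overrides = dict(descriptor.get("params", {}))
    if name not in CLASSIFIERS:
        raise ConfigError(f"unknown classifier {name!r}; roster: {CLASSIFIERS}")
    params = dict(_DEFAULTS["classifiers"].get(name, {}))
    params.update(overrides)
    seeded = dict(params, random_state=seed)
    factories = {
        "gnb": lambda: GaussianNB(**params),
        "knn": lambda: KNeighborsClassifier(**params),
        "dt": lambda: DecisionTreeClassifier(**seeded),
        "lr": lambda: LogisticRegression(**seeded),
        "svm-rbf": lambda: SVC(**seeded),
        "linsvm": lambda: SVC(**seeded),
        "rf": lambda: RandomForestClassifier(**seeded),
        "gbdt": lambda: GradientBoostingClassifier(**seeded),
        "xgb": lambda: XGBClassifier(**seeded),
    }
    return factories[name]()


def _quiet_fit(model, X, y):
    """Fit while muting sklearn's SVC-probability deprecation chatter."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# MinMax normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizerState:
    """Columnwise min/max learned from a training table."""

    names: list[str]
    min_: np.ndarray
    max_: np.ndarray

    def __post_init__(self) -> None:
        if (self.max_ < self.min_).any():
            raise ConfigError("normalizer has max < min")


def minmax_fit(table: FeatureTable) -> NormalizerState:
    """Record the columnwise min and max of a training table."""
    return NormalizerState(
        names=list(table.names),
        min_=table.values.min(axis=0),
        max_=table.values.max(axis=0),
    )


def minmax_apply(state: NormalizerState, table: FeatureTable) -> FeatureTable:
    """Map ``x -> (x - min) / (max - min)`` using training statistics.

    Constant training columns map to 0; values outside the training range
    are *not* clipped, so test rows may fall outside [0, 1].
    """
    if list(table.names) != state.names:
        raise ConfigError("feature names do not match the normalizer state")
    span = state.max_ - state.min_
    safe = np.where(span > 0, span, 1.0)
    values = (table.values - state.min_) / safe
    values[:, span == 0] = 0.0
    return FeatureTable(ids=list(table.ids), names=list(table.names),
                        values=values, labels=table.labels.copy())


def minmax_normalize(table: FeatureTable) -> FeatureTable:
    """Fit-and-apply on the same table (the protocol's Step 1)."""
    return minmax_apply(minmax_fit(table), table)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ConfigError("confusion counts must be nonnegative")
        if self.total < 1:
            raise ConfigError("confusion counts must sum to >= 1")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


@dataclass(frozen=True)
class MetricSet:
    """ACC/SN/SP in [0, 1], MCC in [-1, 1]; ``undefined`` flags ratios
    whose denominator was zero (reported as 0)."""

    ACC: float
    MCC: float
    SN: float
    SP: float
    undefined: tuple[str, ...] = ()

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        scale = 100.0 if percent else 1.0
        return {"ACC": self.ACC * scale, "MCC": self.MCC,
                "SP": self.SP * scale, "SN": self.SN * scale}


def confusion_from_predictions(y_true: Sequence[int],
                               y_pred: Sequence[int]) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ConfigError("prediction/label length mismatch")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """ACC, MCC, SN, SP from confusion counts (total function)."""
    undefined: list[str] = []
    acc = (c.TP + c.TN) / c.total
    if c.TP + c.FN > 0:
        sn = c.TP / (c.TP + c.FN)
    else:
        sn = 0.0
        undefined.append("SN")
    if c.TN + c.FP > 0:
        sp = c.TN / (c.TN + c.FP)
    else:
        sp = 0.0
        undefined.append("SP")
    denom = ((c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN))
    if denom == 0:
        mcc = 0.0
        undefined.append("MCC")
    else:
        mcc = (c.TP * c.TN - c.FN * c.FP) / math.sqrt(denom)
    return MetricSet(ACC=acc, MCC=mcc, SN=sn, SP=sp,
                     undefined=tuple(undefined))


# ---------------------------------------------------------------------------
# Cross-validation and independent-set testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVReport:
    """Per-fold and pooled CV metrics for one classifier on one table."""

    fold_metrics: list[MetricSet]
    fold_counts: list[ConfusionCounts]
    pooled: MetricSet
    pooled_counts: ConfusionCounts
    folds: int
    seed: int
    classifier: str
    fold_safe: bool = False


def _classifier_label(descriptor) -> str:
    return descriptor if isinstance(descriptor, str) else str(descriptor["name"])


def cross_validate(
    table: FeatureTable,
    classifier: str | Mapping[str, object] = "svm-rbf",
    folds: int = 5,
    seed: int = 0,
    fold_safe: bool = False,
) -> CVReport:
    """Stratified k-fold CV with pooled confusion metrics.

    By default the whole table is MinMax-normalized once before folding;
    with ``fold_safe=True`` the normalizer is refit on each training fold.
    """
    counts = np.bincount(table.labels, minlength=2)
    if (counts == 0).any():
        raise ConfigError("cross-validation needs both classes present")
    if folds > counts.min():
        raise ConfigError(
            f"folds={folds} exceeds minority class count {counts.min()}"
        )
    if not fold_safe:
        table = minmax_normalize(table)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_counts: list[ConfusionCounts] = []
    for train_idx, test_idx in skf.split(table.values, table.labels):
        X_train, X_test = table.values[train_idx], table.values[test_idx]
        if fold_safe:
            scaler = MinMaxScaler().fit(X_train)
            X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
        model = _quiet_fit(make_classifier(classifier, seed=seed),
                           X_train, table.labels[train_idx])
        pred = model.predict(X_test)
        fold_counts.append(
            confusion_from_predictions(table.labels[test_idx], pred)
        )
    pooled_counts = fold_counts[0]
    for c in fold_counts[1:]:
        pooled_counts = pooled_counts + c
    return CVReport(
        fold_metrics=[compute_metrics(c) for c in fold_counts],
        fold_counts=fold_counts,
        pooled=compute_metrics(pooled_counts),
        pooled_counts=pooled_counts,
        folds=folds,
        seed=seed,
        classifier=_classifier_label(classifier),
        fold_safe=fold_safe,
    )


@dataclass
class FittedModel:
    """A trained classifier bound to its feature subset and normalizer."""

    names: list[str]
    normalizer: NormalizerState
    estimator: object
    classifier: str

    def _prepare(self, table: FeatureTable) -> np.ndarray:
        sub = table if list(table.names) == self.names else \
            table.subset(self.names)
        return minmax_apply(self.normalizer, sub).values

    def predict(self, table: FeatureTable) -> np.ndarray:
        return np.asarray(self.estimator.predict(self._prepare(table)))

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        if not hasattr(self.estimator, "predict_proba"):
            raise ConfigError(
                f"classifier {self.classifier!r} has no probability output"
            )
        return np.asarray(self.estimator.predict_proba(self._prepare(table)))


def fit_model(table: FeatureTable,
              classifier: str | Mapping[str, object] = "svm-rbf",
              seed: int = 0) -> FittedModel:
    """Fit the classifier on the whole table (normalizer fit on it too)."""
    state = minmax_fit(table)
    model = _quiet_fit(make_classifier(classifier, seed=seed),
                       minmax_apply(state, table).values, table.labels)
    return FittedModel(names=list(table.names), normalizer=state,
                       estimator=model,
                       classifier=_classifier_label(classifier))


def fit_and_test(
    train: FeatureTable,
    test: FeatureTable,
    classifier: str | Mapping[str, object] = "svm-rbf",
    seed: int = 0,
) -> tuple[FittedModel, MetricSet]:
    """Train on the full training table, score an independent test set.

    The normalizer is fit on the training table only and applied,
    unclipped, to the test features.
    """
    if list(train.names) != list(test.names):
        raise ConfigError("train/test feature names do not match")
    fitted = fit_model(train, classifier, seed=seed)
    pred = fitted.predict(test)
    return fitted, compute_metrics(confusion_from_predictions(test.labels, pred))
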