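"""Random-forest toxicity classification and its evaluation metrics.

The classifier follows the statsmodels model/results idiom:
:class:`ToxinClassifier` holds the data and hyperparameters,
``fit()`` returns a :class:`ToxinClassifierResults` carrying the fitted
ensemble, its out-of-bag (OOB) error, and prediction/evaluation methods.

The positive class is *toxin* throughout. A molecule is called toxic when
the fraction of trees voting toxin exceeds 0.5 (strictly); exactly 0.5 is
called non-toxic.

Metrics are the standard confusion-matrix bundle:

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)        accuracy    = (TP+TN)/total
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator is zero is reported as ``None`` and flagged in
``undefined`` rather than silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .featurize import FeatureTable, POSITIVE_LABEL

ModelKind = Literal["descriptor", "fingerprint", "hybrid"]

CALL_THRESHOLD = 0.5


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    """Tally a confusion matrix; toxin (1) is the positive class."""
    labels = np.asarray(labels)
    calls = np.asarray(calls)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls differ in length")
    pos = labels == POSITIVE_LABEL
    called = calls == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(pos & called)),
        tn=int(np.sum(~pos & ~called)),
        fp=int(np.sum(~pos & called)),
        fn=int(np.sum(pos & ~called)),
    )


@dataclass(frozen=True)
class PerformanceReport:
    """The five-metric evaluation bundle plus optional ROC AUC.

    Undefined metrics (zero denominator) are None with their names listed
    in ``undefined``.
    """

    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    mcc: float | None
    roc_auc: float | None = None
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "roc_auc": self.roc_auc,
        }


def performance(counts: ConfusionCounts, roc_auc: float | None = None) -> PerformanceReport:
    """Evaluate the metric bundle from confusion counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    acc = ratio(tp + tn, counts.total, "accuracy")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return PerformanceReport(
        counts, sens, spec, prec, acc, mcc, roc_auc, tuple(undefined)
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def implied_counts(
    sensitivity: float, specificity: float, precision: float, n_negative: float = 1.0
) -> ConfusionCounts:
    """Reconstruct (fractional) confusion counts from three metrics.

    Sensitivity, specificity and precision over-determine the class ratio
    P/N = precision*(1-specificity) / (sensitivity*(1-precision)); with
    the ratio fixed, accuracy and MCC follow. Used to cross-check printed
    performance tables without the underlying data. Returns counts scaled
    so that negatives = ``n_negative`` (fractional counts are fine for the
    ratio-based metrics).
    """

    @dataclass(frozen=True)
    class _FracCounts(ConfusionCounts):
        tp: float
        tn: float
        fp: float
        fn: float

        def __post_init__(self):  # allow fractional values
            if min(self.tp, self.tn, self.fp, self.fn) < 0:
                raise ValueError("negative implied count")

    if not (0 < sensitivity <= 1 and 0 <= specificity < 1 and 0 < precision < 1):
        raise ValueError("metrics must pin down a finite class ratio")
    p_over_n = precision * (1 - specificity) / (sensitivity * (1 - precision))
    p = p_over_n * n_negative
    return _FracCounts(
        tp=sensitivity * p,
        fn=(1 - sensitivity) * p,
        tn=specificity * n_negative,
        fp=(1 - specificity) * n_negative,
    )


# --------------------------------------------------------------------------
# model / results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Prediction:
    molecule_id: str
    toxin_probability: float
    call: Literal["toxic", "nontoxic"]
    model_kind: str


def _infer_kind(kinds: dict[str, str], features: Sequence[str]) -> ModelKind:
    present = {kinds[f] for f in features}
    if present == {"descriptor"}:
        return "descriptor"
    if present == {"fingerprint"}:
        return "fingerprint"
    return "hybrid"


class ToxinClassifier:
    """Random-forest toxin/non-toxin classifier specification.

    Parameters
    ----------
    table : FeatureTable
        Training table with binary labels (1 = toxin).
    features : sequence of str, optional
        Feature subset to train on; defaults to all table columns.
    mtry : int, optional
        Candidate features per split; default floor(sqrt(n_features)).
    ntree : int
        Number of trees (default 1000).
    """

    def __init__(
        self,
        table: FeatureTable,
        features: Sequence[str] | None = None,
        mtry: int | None = None,
        ntree: int = 1000,
    ):
        if table.labels is None:
            raise ValueError("training table has no labels")
        if table.labels.nunique() < 2:
            raise ValueError("training data contains a single class")
        self.table = table
        self.features = list(features) if features is not None else table.feature_names
        missing = [f for f in self.features if f not in table.X.columns]
        if missing:
            raise KeyError(f"features not in table: {missing[:5]}")
        if mtry is None:
            mtry = max(1, int(math.isqrt(len(self.features))))
        if mtry > len(self.features):
            raise ValueError(f"mtry={mtry} exceeds {len(self.features)} features")
        self.mtry = mtry
        self.ntree = ntree
        self.kind: ModelKind = _infer_kind(table.kinds, self.features)

    def fit(self, seed: int = 0) -> "ToxinClassifierResults":
        X = self.table.X[self.features].to_numpy(dtype=np.float64)
        y = self.table.labels.to_numpy()
        est = RandomForestClassifier(
            n_estimators=self.ntree,
            max_features=self.mtry,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        est.fit(X, y)
        return ToxinClassifierResults(self, est, seed)


class ToxinClassifierResults:
    """Fitted toxicity classifier with OOB diagnostics."""

    def __init__(self, model: ToxinClassifier, estimator: RandomForestClassifier, seed: int):
        self.model = model
        self.estimator = estimator
        self.seed = seed
        self.oob_error_ = 1.0 - float(estimator.oob_score_)
        self.class_ratio_ = float(
            (model.table.labels == POSITIVE_LABEL).sum()
            / max(1, (model.table.labels != POSITIVE_LABEL).sum())
        )

    # -- prediction --------------------------------------------------------
    def predict_proba(self, table: FeatureTable) -> pd.Series:
        """Toxin probability = fraction of trees voting toxin, per row."""
        missing = [f for f in self.model.features if f not in table.X.columns]
        if missing:
            raise KeyError(f"query table lacks model features: {missing[:5]}")
        X = table.X[self.model.features].to_numpy(dtype=np.float64)
        pos_col = list(self.estimator.classes_).index(POSITIVE_LABEL)
        proba = self.estimator.predict_proba(X)[:, pos_col]
        return pd.Series(proba, index=table.X.index, name="toxin_probability")

    def predict(self, table: FeatureTable) -> list[Prediction]:
        proba = self.predict_proba(table)
        return [
            Prediction(
                str(mid),
                float(p),
                "toxic" if p > CALL_THRESHOLD else "nontoxic",
                self.model.kind,
            )
            for mid, p in proba.items()
        ]

    # -- evaluation --------------------------------------------------------
    def oob_performance(self) -> PerformanceReport:
        """Metric bundle computed from out-of-bag votes on the training set."""
        y = self.model.table.labels.loc[self.model.table.X.index].to_numpy()
        pos_col = list(self.estimator.classes_).index(POSITIVE_LABEL)
        proba = self.estimator.oob_decision_function_[:, pos_col]
        ok = ~np.isnan(proba)
        calls = (proba[ok] > CALL_THRESHOLD).astype(int)
        auc = roc_auc(y[ok], proba[ok]) if len(np.unique(y[ok])) == 2 else None
        return performance(confusion(y[ok], calls), roc_auc=auc)

    def performance_on(self, table: FeatureTable) -> PerformanceReport:
        if table.labels is None:
            raise ValueError("evaluation table has no labels")
        proba = self.predict_proba(table)
        y = table.labels.to_numpy()
        calls = (proba.to_numpy() > CALL_THRESHOLD).astype(int)
        auc = roc_auc(y, proba.to_numpy()) if len(np.unique(y)) == 2 else None
        return performance(confusion(y, calls), roc_auc=auc)

    def summary(self) -> str:
        rep = self.oob_performance()
        lines = [
            "Toxin random-forest classifier",
            "==============================",
            f"kind:        {self.model.kind}",
            f"features:    {len(self.model.features)}",
            f"mtry:        {self.model.mtry}",
            f"ntree:       {self.model.ntree}",
            f"seed:        {self.seed}",
            f"class ratio: {self.class_ratio_:.2f} (toxin:nontoxin)",
            f"OOB error:   {self.oob_error_:.4f}",
            "OOB metrics:",
        ]
        for k, v in rep.as_dict().items():
            lines.append(f"  {k:<12} {'undefined' if v is None else f'{v:.4f}'}")
        return "\n".join(lines)


def train_classifier(
    table: FeatureTable,
    features: Sequence[str] | None = None,
    mtry: int | None = None,
    ntree: int = 1000,
    seed: int = 0,
) -> ToxinClassifierResults:
    """Convenience wrapper: specify and fit in one call."""
    return ToxinClassifier(table, features, mtry, ntree).fit(seed)


def predict_proba(results: ToxinClassifierResults, table: FeatureTable) -> list[Prediction]:
    """Per-molecule toxin probabilities and calls from a fitted model."""
    return results.predict(table)
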