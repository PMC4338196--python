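"""Diagnostic performance: confusion-matrix metrics, ROC/AUC, correlation.

Percentages are reported to one decimal (half-up, the convention of the
published tables) while full precision is retained internally.  The AUC is
the trapezoid area under the empirical ROC curve, which equals the
Mann-Whitney concordance probability with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve


def round_pct(x: float, decimals: int = 1) -> float:
    """Half-up percentage rounding (table-reporting convention)."""
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """2x2 classification counts with percentage metrics.

    ``sensitivity``/``specificity``/``accuracy`` are percentages at full
    precision; the ``*_reported`` properties give the 1-decimal half-up
    values used in reports.  A metric whose denominator is empty is NaN.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total if self.total else float("nan")

    @property
    def sensitivity_reported(self) -> float:
        return round_pct(self.sensitivity)

    @property
    def specificity_reported(self) -> float:
        return round_pct(self.specificity)

    @property
    def accuracy_reported(self) -> float:
        return round_pct(self.accuracy)


def confusion_metrics(predictions, labels) -> ConfusionCounts:
    """Confusion counts of binary predictions against binary labels
    (1 = cancer side / predicted positive)."""
    predictions = np.asarray(predictions).astype(int)
    labels = np.asarray(labels).astype(int)
    if predictions.size == 0:
        raise ValueError("empty input")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    return ConfusionCounts(
        tp=int(((predictions == 1) & (labels == 1)).sum()),
        fn=int(((predictions == 0) & (labels == 1)).sum()),
        fp=int(((predictions == 1) & (labels == 0)).sum()),
        tn=int(((predictions == 0) & (labels == 0)).sum()),
    )


@dataclass
class ROCCurve:
    """Empirical ROC curve: thresholds with their FPR/TPR, and the AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve and trapezoid AUC of continuous scores.

    The AUC equals the Mann-Whitney estimate
    (#concordant + 0.5 #tied) / (n1 * n0): the probability that a random
    cancer sample scores above a random control.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation between two covariate vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance in one of the inputs")
    r, _ = sps.pearsonr(x, y)
    return float(r)
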