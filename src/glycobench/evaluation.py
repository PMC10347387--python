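"""Model evaluation: the economic Model Benefit statistic plus AUC, AUPRC,
accuracy, calibration and decision-curve analysis.

Model Benefit (MB) prices the confusion matrix of an HbA1c-screening
classifier.  With a per-test fee ``c_t`` (default 73 yuan) and a
false-negative cost ``c_m`` -- the per-patient excess cost of therapeutic
inertia when a poorly controlled patient goes undetected (default 786.77
yuan) --

    TC = N * c_t                                   (test everyone)
    MC = (TP + FP) * c_t + FN * c_m - TN * c_t     (model-guided testing)
    MB = TC - MC

which collapses to MB = 2*c_t*TN - (c_m - c_t)*FN: the statistic rewards
averted tests and penalizes missed poorly-controlled patients, and is
independent of TP/FP at fixed N.  Currency arithmetic is exact decimal,
rounded to cents at report time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "CostModel",
    "ConfusionCounts",
    "BenefitReport",
    "EvaluationReport",
    "confusion_at_threshold",
    "model_benefit",
    "roc_auc",
    "pr_auc",
    "accuracy",
    "precision",
    "recall",
    "calibration_curve",
    "decision_curve",
    "optimal_mb_threshold",
    "evaluate_scores",
]

_CENT = Decimal("0.01")


@dataclass(frozen=True)
class CostModel:
    test_fee: float = 73.0
    miss_cost: float = 786.77
    currency: str = "¥"

    def __post_init__(self) -> None:
        if self.test_fee < 0:
            raise ValueError("test_fee must be >= 0")
        if self.miss_cost < self.test_fee:
            raise ValueError(
                "miss_cost below test_fee makes the screen economically "
                "meaningless"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class BenefitReport:
    tc: float
    mc: float
    mb: float
    currency: str = "¥"


@dataclass(frozen=True)
class EvaluationReport:
    benefit: BenefitReport
    counts: ConfusionCounts
    auc: float
    auprc: float
    accuracy: float
    precision: float
    recall: float
    calibration: tuple[tuple[float, float, int], ...]
    dca: tuple[tuple[float, float, float], ...]
    threshold: float


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty score list")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def confusion_at_threshold(
    scores, labels, threshold: float = 0.5
) -> ConfusionCounts:
    """Tally the confusion matrix; a score >= threshold predicts positive."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def model_benefit(counts: ConfusionCounts, costs: CostModel = CostModel()) -> BenefitReport:
    fee = Decimal(str(costs.test_fee))
    miss = Decimal(str(costs.miss_cost))
    tc = Decimal(counts.n) * fee
    mc = (
        Decimal(counts.tp) * fee
        + Decimal(counts.fp) * fee
        + Decimal(counts.fn) * miss
        - Decimal(counts.tn) * fee
    )
    mb = tc - mc
    q = lambda d: float(d.quantize(_CENT, rounding=ROUND_HALF_UP))
    return BenefitReport(tc=q(tc), mc=q(mc), mb=q(mb), currency=costs.currency)


def roc_auc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def pr_auc(scores, labels) -> float:
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPRC requires both classes present")
    return float(average_precision_score(labels, scores))


def accuracy(counts: ConfusionCounts) -> float:
    return (counts.tp + counts.tn) / counts.n


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


def calibration_curve(
    scores, labels, bins: int = 10
) -> tuple[tuple[float, float, int], ...]:
    """Equal-width bins: (mean predicted, observed rate, count); empty bins
    omitted."""
    if bins < 2:
        raise ValueError("calibration requires at least 2 bins")
    scores, labels = _check_scores_labels(scores, labels)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, bins - 1)
    points = []
    for b in range(bins):
        in_bin = idx == b
        if not in_bin.any():
            continue
        points.append(
            (
                float(scores[in_bin].mean()),
                float(labels[in_bin].mean()),
                int(in_bin.sum()),
            )
        )
    return tuple(points)


def decision_curve(
    scores, labels, thresholds
) -> tuple[tuple[float, float, float], ...]:
    """Net benefit of acting at each threshold probability pt.

    Returns (pt, net benefit of the model, net benefit of treat-all); the
    treat-none reference is identically zero.  NB = TP/N - (FP/N)*pt/(1-pt)
    with pt doubling as the positivity cutoff.
    """
    scores, labels = _check_scores_labels(scores, labels)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(scores)
    prevalence = labels.mean()
    points = []
    for pt in thresholds:
        counts = confusion_at_threshold(scores, labels, float(pt))
        odds = pt / (1 - pt)
        nb = counts.tp / n - (counts.fp / n) * odds
        nb_all = prevalence - (1 - prevalence) * odds
        points.append((float(pt), float(nb), float(nb_all)))
    return tuple(points)


def optimal_mb_threshold(
    scores, labels, costs: CostModel = CostModel()
) -> float:
    """Scan score cutpoints and return the threshold maximizing MB.

    Intended to run on training-partition predictions; the chosen threshold
    is then applied frozen to the test partition.  Ties go to the lowest
    threshold.
    """
    scores, labels = _check_scores_labels(scores, labels)
    candidates = np.unique(np.concatenate([[0.0, 0.5, 1.0], scores]))
    best_t, best_mb = 0.5, -np.inf
    for t in candidates:
        mb = model_benefit(confusion_at_threshold(scores, labels, float(t)), costs).mb
        if mb > best_mb:
            best_t, best_mb = float(t), mb
    return best_t


def evaluate_scores(
    scores,
    labels,
    costs: CostModel = CostModel(),
    threshold: float = 0.5,
    bins: int = 10,
    dca_thresholds=None,
) -> EvaluationReport:
    """Full test-set evaluation of predicted probabilities."""
    counts = confusion_at_threshold(scores, labels, threshold)
    if dca_thresholds is None:
        dca_thresholds = np.linspace(0.05, 0.95, 19)
    return EvaluationReport(
        benefit=model_benefit(counts, costs),
        counts=counts,
        auc=roc_auc(scores, labels),
        auprc=pr_auc(scores, labels),
        accuracy=accuracy(counts),
        precision=precision(counts),
        recall=recall(counts),
        calibration=calibration_curve(scores, labels, bins),
        dca=decision_curve(scores, labels, dca_thresholds),
        threshold=threshold,
    )
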