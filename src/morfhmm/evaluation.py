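"""Evaluation metrics for per-residue MoRF predictions.

Three metrics are reported over pooled residues and per-sequence tracks:

* **AUC** — area under the empirical ROC curve; equal to the Mann-Whitney
  probability that a random MoRF residue outscores a random non-MoRF residue
  (ties counted one half).
* **FPR / accuracy at fixed TPR** — the false-positive rate (and overall
  accuracy) at the operating threshold of the empirical ROC, where the
  threshold is the largest score cutoff whose true-positive rate reaches the
  requested level (no interpolation between ROC vertices). Default operating
  points: TPR = 0.222 and 0.389.
* **Success rate** — the fraction of sequences in which the mean propensity
  over true MoRF residues strictly exceeds the mean over non-MoRF residues;
  ties count as failure, and sequences lacking one of the two classes are
  excluded from the denominator.

All residues outside annotated MoRFs — flanks included — count as negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

DEFAULT_TPR_LEVELS = (0.222, 0.389)


class SingleClassError(ValueError):
    """Raised when scores cannot be ranked because only one class is present."""


def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise SingleClassError("both classes must be present")
    return labels


def roc_auc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve (= pairwise rank statistic)."""
    labels = _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _operating_point(scores, labels, tpr_level: float):
    """Threshold/FPR/TPR at the most conservative cutoff with TPR >= level."""
    if not 0.0 < tpr_level <= 1.0:
        raise ValueError(f"tpr_level {tpr_level} outside (0, 1]")
    labels = _check_two_classes(labels)
    fpr, tpr, thresholds = roc_curve(
        labels, np.asarray(scores, dtype=float), drop_intermediate=False
    )
    idx = int(np.argmax(tpr >= tpr_level))
    return thresholds[idx], float(fpr[idx]), float(tpr[idx])


def fpr_at_tpr(scores, labels, tpr_level: float) -> float:
    """False-positive rate at the threshold reaching the requested TPR."""
    _, fpr, _ = _operating_point(scores, labels, tpr_level)
    return fpr


def accuracy_at_tpr(scores, labels, tpr_level: float) -> float:
    """(TP + TN) / (P + N) at the same threshold rule as :func:`fpr_at_tpr`."""
    threshold, _, _ = _operating_point(scores, labels, tpr_level)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    return float(np.mean(pred == labels.astype(bool)))


def success_rate(per_sequence: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Fraction of sequences whose MoRF residues outscore non-MoRF on average.

    The comparison is strict; sequences with no MoRF or no non-MoRF residue
    are skipped (with a logged count) and do not enter the denominator.
    """
    if not per_sequence:
        raise ValueError("no sequences to evaluate")
    wins = 0
    considered = 0
    skipped = 0
    for scores, labels in per_sequence:
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels).astype(bool)
        if labels.all() or not labels.any():
            skipped += 1
            continue
        considered += 1
        if scores[labels].mean() > scores[~labels].mean():
            wins += 1
    if skipped:
        logger.warning("success_rate: skipped %d sequence(s) lacking one class", skipped)
    if considered == 0:
        raise ValueError("every sequence lacked one of the two classes")
    return wins / considered


@dataclass
class EvaluationReport:
    """Aggregate metrics over a prediction run."""

    auc: float
    success_rate: float
    fpr_at_tpr: dict[float, float]
    accuracy_at_tpr: dict[float, float]
    n_pos: int
    n_neg: int
    n_sequences: int = 0
    tpr_levels: tuple[float, ...] = field(default=DEFAULT_TPR_LEVELS)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "success_rate": self.success_rate,
            "fpr_at_tpr": {str(k): v for k, v in self.fpr_at_tpr.items()},
            "accuracy_at_tpr": {str(k): v for k, v in self.accuracy_at_tpr.items()},
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_sequences": self.n_sequences,
        }


def evaluate(
    per_sequence: list[tuple[np.ndarray, np.ndarray]],
    tpr_levels: tuple[float, ...] = DEFAULT_TPR_LEVELS,
) -> EvaluationReport:
    """Full report from per-sequence (scores, binary MoRF labels) pairs.

    Residue-level metrics (AUC, FPR/accuracy at TPR) pool residues across
    sequences; the success rate stays per-sequence.
    """
    scores = np.concatenate([np.asarray(s, dtype=float) for s, _ in per_sequence])
    labels = np.concatenate([np.asarray(l).astype(int) for _, l in per_sequence])
    return EvaluationReport(
        auc=roc_auc(scores, labels),
        success_rate=success_rate(per_sequence),
        fpr_at_tpr={lv: fpr_at_tpr(scores, labels, lv) for lv in tpr_levels},
        accuracy_at_tpr={lv: accuracy_at_tpr(scores, labels, lv) for lv in tpr_levels},
        n_pos=int(labels.sum()),
        n_neg=int((1 - labels).sum()),
        n_sequences=len(per_sequence),
        tpr_levels=tuple(tpr_levels),
    )
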