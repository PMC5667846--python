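"""Multi-categorical evaluation metrics.

All multi-class metrics are computed from a single K×K confusion matrix
``q`` with rows indexing the true class and columns the predicted class:

* **Accuracy** — trace(q) / Σ q.
* **RCI** (relative classifier information) — an entropy measure of how
  much of the true-label uncertainty the classifier removes:
  [H(true) − H(true | predicted)] / H(true) with natural logarithms.
  This equals the mutual information between truth and prediction
  normalised by the true-label entropy, so a perfect classifier scores
  1 and a constant predictor 0 regardless of class balance.  The
  unnormalised mutual information is also available
  (:func:`rci_unnormalized`).
* **Cohen's kappa** — chance-corrected agreement,
  (N·Σ q_ii − Σ_i row_i·col_i) / (N² − Σ_i row_i·col_i).

Binary screening performance uses ROC analysis: AUC by the trapezoidal
rule over all score thresholds and the Youden index J = sensitivity +
specificity − 1 to pick a balanced operating cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ConfusionMatrix:
    """K×K count matrix; q[i, j] = samples of true class i predicted j."""

    q: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != self.q.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.q < 0).any():
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def n(self) -> float:
        return float(self.q.sum())


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_index: float

    @property
    def sensitivity_at_cutoff(self) -> float:
        i = int(np.argmax(self.thresholds == self.youden_cutoff))
        return float(self.sensitivity[i])

    @property
    def specificity_at_cutoff(self) -> float:
        i = int(np.argmax(self.thresholds == self.youden_cutoff))
        return float(self.specificity[i])


def confusion(true_labels, predicted_labels, n_classes: int,
              class_names: list[str] | None = None) -> ConfusionMatrix:
    """Count matrix of (true, predicted) label pairs."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.size == 0:
        raise ValueError("empty label arrays")
    if t.shape != p.shape:
        raise ValueError("true and predicted labels must have equal length")
    if t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    q = np.zeros((n_classes, n_classes))
    np.add.at(q, (t, p), 1)
    return ConfusionMatrix(q=q, class_names=class_names)


def _as_q(cm) -> np.ndarray:
    q = cm.q if isinstance(cm, ConfusionMatrix) else np.asarray(cm, dtype=float)
    if q.sum() == 0:
        raise ValueError("confusion matrix has no observations")
    return q


def accuracy(cm) -> float:
    q = _as_q(cm)
    return float(np.trace(q) / q.sum())


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def rci_unnormalized(cm) -> float:
    """Mutual information I(true; predicted) in nats: H(true) − H(true|pred)."""
    q = _as_q(cm)
    n = q.sum()
    h_true = _entropy(q.sum(axis=1) / n)
    col = q.sum(axis=0)
    h_cond = 0.0
    for j in range(q.shape[1]):
        if col[j] > 0:
            h_cond += (col[j] / n) * _entropy(q[:, j] / col[j])
    return h_true - h_cond


def rci(cm) -> float:
    """Relative classifier information: I(true; predicted) / H(true).

    Perfect diagonal → 1; a constant predictor → 0.  If the true-label
    margin is degenerate (H(true) = 0) the value is 0 by convention.
    """
    q = _as_q(cm)
    h_true = _entropy(q.sum(axis=1) / q.sum())
    if h_true == 0:
        return 0.0
    return rci_unnormalized(cm) / h_true


def kappa(cm) -> float:
    """Cohen's kappa: (N·Σ q_ii − Σ row_i·col_i) / (N² − Σ row_i·col_i)."""
    q = _as_q(cm)
    n = q.sum()
    chance = float((q.sum(axis=1) * q.sum(axis=0)).sum())
    denom = n * n - chance
    if denom == 0:
        warnings.warn("degenerate margins: kappa undefined, returning 0")
        return 0.0
    return float((n * np.trace(q) - chance) / denom)


def roc_auc_youden(scores, truth) -> RocResult:
    """ROC analysis of a binary score with Youden-index cut-off.

    A sample is called positive when its score is ≥ the threshold; the
    threshold sweep covers every unique score plus a sentinel above the
    maximum.  AUC is the trapezoidal area over (FPR, TPR); the Youden
    cut-off maximises sensitivity + specificity − 1, taking the lowest
    threshold on ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    pos = int((y == 1).sum())
    neg = int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    uniq = np.unique(s)
    thresholds = np.concatenate([[uniq.max() + 1.0], uniq[::-1]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, th in enumerate(thresholds):
        called = s >= th
        sens[i] = (called & (y == 1)).sum() / pos
        spec[i] = (~called & (y == 0)).sum() / neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))

    j = sens + spec - 1.0
    jmax = j.max()
    # ties -> lowest threshold; thresholds array is decreasing
    cut_i = int(np.flatnonzero(np.isclose(j, jmax))[-1])
    return RocResult(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=auc, youden_cutoff=float(thresholds[cut_i]),
                     youden_index=float(jmax))
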