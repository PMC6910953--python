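"""Score fusion (logistic regression) and evaluation metrics.

Fusion combines a speaker's scores from several manner groupings — all
produced with the same PLP order F and mixture size G — into a single
log-odds score via an L2-regularised logistic regression fit on training
speakers only.  Metrics follow the usual clinical-screening conventions:
accuracy with a 95 % Wald binomial confidence interval, AUC as the
Mann-Whitney statistic (ties counted 1/2), and sensitivity / specificity
with PD as the positive class.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .store import CTRL, PD

#: L2 penalty strength 1/C used in fusion (small, fixed; keeps collinear or
#: constant score components from blowing up the solver)
FUSION_C = 1e4


@dataclass
class EvalResult:
    """Metrics for one (approach, grouping-or-tuple, task, F, G) cell."""

    accuracy: float            # percent
    ci_halfwidth: float        # percent, 95 % Wald
    auc: float
    sensitivity: float
    specificity: float
    n_test_speakers: int
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    metadata: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "accuracy": self.accuracy,
            "ci_halfwidth": self.ci_halfwidth,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_test_speakers": self.n_test_speakers,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
        }
        row.update(self.metadata)
        return row


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic of PD vs Ctrl scores, ties 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == PD
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    labels: np.ndarray,
    scores: np.ndarray,
    decisions: np.ndarray,
    metadata: dict | None = None,
) -> EvalResult:
    """Confusion-count metrics at speaker (or utterance) level.

    ``decisions`` are the thresholded class calls; ``scores`` feed the AUC
    (threshold-free).  PD is the positive class.
    """
    labels = np.asarray(labels)
    decisions = np.asarray(decisions)
    if labels.shape != decisions.shape:
        raise ValueError("labels and decisions must align")
    pos = labels == PD
    if not pos.any() or pos.all():
        raise ValueError("metrics need at least one speaker per class")
    tp = int(np.sum(pos & (decisions == PD)))
    fn = int(np.sum(pos & (decisions != PD)))
    tn = int(np.sum(~pos & (decisions == CTRL)))
    fp = int(np.sum(~pos & (decisions != CTRL)))
    n = labels.size
    p_hat = (tp + tn) / n
    ci = 1.96 * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return EvalResult(
        accuracy=100.0 * p_hat,
        ci_halfwidth=100.0 * ci,
        auc=auc_score(scores, labels),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        n_test_speakers=n,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        metadata=metadata or {},
    )


def fuse_scores(
    train_scores: np.ndarray,
    train_labels: np.ndarray,
    test_scores: np.ndarray,
) -> np.ndarray:
    """Logistic-regression fusion of per-speaker score tuples.

    Fit on training speakers (both classes required), return the linear
    predictor (log-odds of PD) for the test speakers; thresholding and
    metrics are handled downstream exactly as for single scores.
    """
    train_scores = np.atleast_2d(np.asarray(train_scores, dtype=np.float64))
    test_scores = np.atleast_2d(np.asarray(test_scores, dtype=np.float64))
    y = (np.asarray(train_labels) == PD).astype(int)
    if y.min() == y.max():
        raise ValueError("fusion training set must contain both classes")
    clf = LogisticRegression(C=FUSION_C, solver="lbfgs", max_iter=5000, tol=1e-10)
    clf.fit(train_scores, y)
    return clf.decision_function(test_scores)
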