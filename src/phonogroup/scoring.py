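"""Utterance scoring and threshold calibration.

An utterance u with frames x_1..x_N is scored against the two adapted
models as the average per-frame log-likelihood

    L_u^c = (1/N) sum_n log p(x_n | Gamma^c),   c in {PD, Ctrl},

and the decision statistic is the log-likelihood ratio
L_u = L_u^PD - L_u^Ctrl.  The operating threshold lambda is calibrated at
the equal-error-rate point of the adaptation (training-fold) scores; an
utterance is called PD iff its score is strictly greater than lambda.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gmm import DiagGMM
from .store import CTRL, PD


class UnscorableUtterance(ValueError):
    """Raised when an utterance has no frames to score (possible after
    grouping); callers exclude such utterances from metrics and log them."""


@dataclass
class ScoreRecord:
    utterance_id: str
    speaker_id: str
    true_class: str
    llk_pd: float
    llk_ctrl: float
    llr: float
    grouping: str = "none"
    F: int = 0
    G: int = 0
    n_frames_scored: int = 0


@dataclass
class DecisionThreshold:
    """EER operating point: threshold lambda and the EER attained there."""

    lam: float
    eer: float
    source: str = ""


def score_utterance(
    frames: np.ndarray,
    model_pd: DiagGMM,
    model_ctrl: DiagGMM,
    *,
    utterance_id: str = "",
    speaker_id: str = "",
    true_class: str = "",
    grouping: str = "none",
    F: int = 0,
    G: int = 0,
) -> ScoreRecord:
    """Average per-frame log-likelihood under each model and their ratio."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if frames.shape[0] == 0:
        raise UnscorableUtterance(f"utterance {utterance_id!r} has no frames")
    lpd = float(np.mean(model_pd.log_density(frames)))
    lct = float(np.mean(model_ctrl.log_density(frames)))
    return ScoreRecord(
        utterance_id,
        speaker_id,
        true_class,
        lpd,
        lct,
        lpd - lct,
        grouping,
        F,
        G,
        int(frames.shape[0]),
    )


def eer_threshold(
    scores: np.ndarray, labels: np.ndarray, source: str = ""
) -> DecisionThreshold:
    """Equal-error-rate calibration of the decision threshold.

    Decisions are score > lambda => PD, so FPR(lambda) = P(Ctrl > lambda)
    and FNR(lambda) = P(PD <= lambda).  Candidate thresholds are the open
    intervals between consecutive distinct pooled scores (plus the two
    unbounded ends); lambda is the midpoint of the interval minimising
    |FPR - FNR| (ties broken towards smaller total error, then towards the
    widest contiguous run of minimisers), and EER = (FPR + FNR)/2 there.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pd_scores = np.sort(scores[labels == PD])
    ct_scores = np.sort(scores[labels == CTRL])
    if pd_scores.size == 0 or ct_scores.size == 0:
        raise ValueError("both classes must be present to calibrate a threshold")
    s = np.unique(scores)
    # interval k: ( edges[k], edges[k+1] ), with sentinels at the ends
    edges = np.concatenate([[s[0] - 2.0], s, [s[-1] + 2.0]])
    cand = 0.5 * (edges[:-1] + edges[1:])
    fpr = 1.0 - np.searchsorted(ct_scores, cand, side="right") / ct_scores.size
    fnr = np.searchsorted(pd_scores, cand, side="right") / pd_scores.size
    diff = np.abs(fpr - fnr)
    total = fpr + fnr
    dmin = diff.min()
    best = diff <= dmin + 1e-12
    tmin = total[best].min()
    best &= total <= tmin + 1e-12
    idx = np.flatnonzero(best)
    # widest contiguous run of equally good intervals; first such run
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    run = max(runs, key=len)
    lo, hi = edges[run[0]], edges[run[-1] + 1]
    lam = 0.5 * (lo + hi)
    eer = 0.5 * float(total[run[0]])
    return DecisionThreshold(float(lam), eer, source)


def decide(llr: float, threshold: DecisionThreshold) -> str:
    """PD iff the score is strictly higher than lambda."""
    return PD if llr > threshold.lam else CTRL


def speaker_score(records: list[ScoreRecord]) -> float:
    """Speaker-level score: mean of the per-utterance log-likelihood ratios
    (aggregation used for speaker metrics and for score fusion)."""
    if not records:
        raise UnscorableUtterance("speaker has no scorable utterances")
    return float(np.mean([r.llr for r in records]))
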