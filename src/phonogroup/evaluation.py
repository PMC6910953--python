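"""Experiment orchestration: approaches, CV folds, cross-corpora rounds.

Four detection schemes differ only in where phonemic grouping is applied:

============  ==================  ============================
approach      background corpus   adaptation / test corpus
============  ==================  ============================
baseline      ungrouped           ungrouped
raw_phon      ungrouped           grouped
phon_phon     grouped             grouped
phon_raw      grouped             ungrouped
============  ==================  ============================

``phon_raw`` deliberately scores *all* test frames: grouping only shapes
the background model, so components dominated by the target manner class
exist but no test material is discarded.

Cross-validation is speaker-disjoint and class-stratified (11 folds by
default); the decision threshold of each fold is calibrated at the EER of
the training-fold utterance scores, so no test information leaks into the
operating point.  Cross-corpora validation adapts on two corpora jointly
and tests on the held-out third.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import scoring
from .fusion import EvalResult, compute_metrics
from .gmm import DiagGMM, MapConfig, map_adapt, train_ubm
from .grouping import MannerClass, group_corpus
from .scoring import ScoreRecord, UnscorableUtterance, score_utterance
from .store import CTRL, PD, CorpusStore, merge_stores

logger = logging.getLogger(__name__)

APPROACHES = ("baseline", "raw_phon", "phon_phon", "phon_raw")
F_GRID = (10, 12, 14, 16, 18, 20)
G_GRID = (4, 8, 16, 32, 64, 128, 256)

#: approaches that group the UBM corpus / the adaptation-test corpus
_GROUPS_UBM = ("phon_phon", "phon_raw")
_GROUPS_ADAPT = ("raw_phon", "phon_phon")


@dataclass
class ExperimentSpec:
    approach: str = "baseline"
    grouping: MannerClass | None = None
    F: int = 10                       # nominal PLP order (D = 3F)
    G_grid: tuple = (8,)
    n_folds: int = 11
    fold_seed: int = 0
    map_config: MapConfig = field(default_factory=MapConfig)
    max_ubm_frames: int = 50000       # seeded subsample cap for EM

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.approach == "baseline" and self.grouping is not None:
            raise ValueError("baseline uses no grouping")
        if self.approach != "baseline" and self.grouping is None:
            raise ValueError(f"{self.approach} requires a grouping")


def make_folds(
    speaker_ids: list[str],
    labels: list[str],
    n_folds: int = 11,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """Speaker-level, class-stratified, seeded k-fold partition.

    Returns (train_speakers, test_speakers) per fold; every speaker appears
    in exactly one test fold.
    """
    speaker_ids = list(speaker_ids)
    labels = list(labels)
    if len(speaker_ids) < n_folds:
        raise ValueError(f"{len(speaker_ids)} speakers cannot fill {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = np.asarray(speaker_ids)
    folds = []
    for tr, te in skf.split(ids, np.asarray(labels)):
        folds.append((list(ids[tr]), list(ids[te])))
    return folds


def _prepare(store: CorpusStore, grouping, grouped: bool) -> CorpusStore:
    if not grouped:
        return store
    out, stats = group_corpus(store, grouping)
    if stats["skipped_no_alignment"]:
        raise ValueError(
            f"{stats['skipped_no_alignment']} utterances lack alignments; "
            "grouping on this corpus is impossible"
        )
    return out


def _subsample(X: np.ndarray, cap: int, seed: int) -> np.ndarray:
    if X.shape[0] <= cap:
        return X
    rng = np.random.default_rng(seed)
    return X[rng.choice(X.shape[0], cap, replace=False)]


def _score_store(
    store: CorpusStore,
    model_pd: DiagGMM,
    model_ctrl: DiagGMM,
    grouping,
    F: int,
    G: int,
) -> list[ScoreRecord]:
    records = []
    n_unscorable = 0
    for u in store:
        try:
            records.append(
                score_utterance(
                    u.features.values,
                    model_pd,
                    model_ctrl,
                    utterance_id=u.utterance_id,
                    speaker_id=u.speaker_id,
                    true_class=u.label,
                    grouping=grouping.value if grouping else "none",
                    F=F,
                    G=G,
                )
            )
        except UnscorableUtterance:
            n_unscorable += 1
    if n_unscorable:
        logger.warning("%d utterances unscorable (no frames)", n_unscorable)
    return records


def _speaker_table(records: list[ScoreRecord]) -> dict[str, tuple[str, float]]:
    """speaker -> (true class, mean utterance LLR)."""
    by_speaker: dict[str, list[ScoreRecord]] = {}
    for r in records:
        by_speaker.setdefault(r.speaker_id, []).append(r)
    return {
        spk: (recs[0].true_class, scoring.speaker_score(recs))
        for spk, recs in by_speaker.items()
    }


@dataclass
class ApproachRun:
    """All outputs of one approach over one G grid: per-cell metrics plus
    the raw per-utterance and per-speaker scores for downstream fusion."""

    results: list[EvalResult]
    utterance_results: list[EvalResult]
    score_records: dict[int, list[ScoreRecord]]       # G -> test records
    speaker_scores: dict[int, pd.DataFrame]           # G -> speaker table


def run_approach(
    spec: ExperimentSpec,
    ubm_store: CorpusStore,
    adapt_store: CorpusStore,
) -> ApproachRun:
    """Speaker-disjoint cross-validation of one approach over the G grid."""
    group_ubm = spec.approach in _GROUPS_UBM
    group_adapt = spec.approach in _GROUPS_ADAPT
    ubm_prepped = _prepare(ubm_store, spec.grouping, group_ubm)
    adapt_prepped = _prepare(adapt_store, spec.grouping, group_adapt)

    speaker_labels = adapt_store.speaker_labels()
    speakers = list(speaker_labels)
    folds = make_folds(
        speakers, [speaker_labels[s] for s in speakers], spec.n_folds, spec.fold_seed
    )

    ubm_frames = _subsample(
        ubm_prepped.pooled_frames(), spec.max_ubm_frames, spec.map_config.init_seed
    )
    results, utt_results = [], []
    all_records: dict[int, list[ScoreRecord]] = {}
    speaker_tables: dict[int, pd.DataFrame] = {}
    for G in spec.G_grid:
        ubm = train_ubm(ubm_frames, G, spec.map_config)
        spk_rows = []
        utt_rows = []
        test_records: list[ScoreRecord] = []
        for train_spk, test_spk in folds:
            assert not set(train_spk) & set(test_spk)
            train = adapt_prepped.subset_speakers(train_spk)
            test = adapt_prepped.subset_speakers(test_spk)
            model_pd = map_adapt(ubm, train.pooled_frames(PD), spec.map_config)
            model_ct = map_adapt(ubm, train.pooled_frames(CTRL), spec.map_config)
            train_rec = _score_store(
                train, model_pd, model_ct, spec.grouping, spec.F, G
            )
            lam = scoring.eer_threshold(
                np.array([r.llr for r in train_rec]),
                np.array([r.true_class for r in train_rec]),
                source="training-fold utterance LLRs",
            )
            test_rec = _score_store(test, model_pd, model_ct, spec.grouping, spec.F, G)
            test_records.extend(test_rec)
            for r in test_rec:
                utt_rows.append((r.true_class, r.llr, scoring.decide(r.llr, lam)))
            for spk, (cls, s) in _speaker_table(test_rec).items():
                spk_rows.append((spk, cls, s, scoring.decide(s, lam)))
        meta = {
            "approach": spec.approach,
            "grouping": spec.grouping.value if spec.grouping else "none",
            "F": spec.F,
            "G": G,
            "level": "speaker",
            "mode": "cv",
        }
        labels = np.array([r[1] for r in spk_rows])
        scores_arr = np.array([r[2] for r in spk_rows])
        decisions = np.array([r[3] for r in spk_rows])
        results.append(compute_metrics(labels, scores_arr, decisions, dict(meta)))
        u_labels = np.array([r[0] for r in utt_rows])
        u_scores = np.array([r[1] for r in utt_rows])
        u_dec = np.array([r[2] for r in utt_rows])
        utt_results.append(
            compute_metrics(
                u_labels, u_scores, u_dec, {**meta, "level": "utterance"}
            )
        )
        all_records[G] = test_records
        speaker_tables[G] = pd.DataFrame(
            spk_rows, columns=["speaker_id", "class", "score", "decision"]
        )
    return ApproachRun(results, utt_results, all_records, speaker_tables)


def run_cross_corpora(
    spec: ExperimentSpec,
    ubm_store: CorpusStore,
    corpora: dict[str, CorpusStore],
) -> list[EvalResult]:
    """Adapt-on-two / test-on-one rounds over >= 3 corpora.

    Only the ungrouped-adaptation approaches (baseline, phon_raw) are
    eligible: the test corpus may lack alignments.  The threshold is
    calibrated on the pooled adaptation corpora's utterance scores.
    """
    if len(corpora) < 3:
        raise ValueError("cross-corpora validation needs at least 3 corpora")
    if spec.approach not in ("baseline", "phon_raw"):
        raise ValueError("cross-corpora supports baseline and phon_raw only")
    ubm_prepped = _prepare(ubm_store, spec.grouping, spec.approach == "phon_raw")
    ubm_frames = _subsample(
        ubm_prepped.pooled_frames(), spec.max_ubm_frames, spec.map_config.init_seed
    )
    results = []
    names = sorted(corpora)
    for G in spec.G_grid:
        ubm = train_ubm(ubm_frames, G, spec.map_config)
        for test_name in names:
            adapt_names = [n for n in names if n != test_name]
            adapt = merge_stores([corpora[n] for n in adapt_names])
            test = corpora[test_name]
            overlap = set(adapt.speakers()) & set(test.speakers())
            assert not overlap, f"speakers shared across corpora: {overlap}"
            model_pd = map_adapt(ubm, adapt.pooled_frames(PD), spec.map_config)
            model_ct = map_adapt(ubm, adapt.pooled_frames(CTRL), spec.map_config)
            adapt_rec = _score_store(
                adapt, model_pd, model_ct, spec.grouping, spec.F, G
            )
            lam = scoring.eer_threshold(
                np.array([r.llr for r in adapt_rec]),
                np.array([r.true_class for r in adapt_rec]),
                source=f"adaptation corpora {adapt_names}",
            )
            test_rec = _score_store(test, model_pd, model_ct, spec.grouping, spec.F, G)
            spk = _speaker_table(test_rec)
            labels = np.array([cls for cls, _ in spk.values()])
            scores_arr = np.array([s for _, s in spk.values()])
            decisions = np.array([scoring.decide(s, lam) for _, s in spk.values()])
            results.append(
                compute_metrics(
                    labels,
                    scores_arr,
                    decisions,
                    {
                        "approach": spec.approach,
                        "grouping": spec.grouping.value if spec.grouping else "none",
                        "F": spec.F,
                        "G": G,
                        "level": "speaker",
                        "mode": "cross_corpora",
                        "test_corpus": test_name,
                        "adapt_corpora": "+".join(adapt_names),
                    },
                )
            )
    return results


def select_best(results: list[EvalResult]) -> EvalResult:
    """Best grid cell: highest accuracy, ties broken by AUC, then by the
    more parsimonious model (smaller G, then smaller F)."""
    if not results:
        raise ValueError("no results to select from")
    return max(
        results,
        key=lambda r: (
            r.accuracy,
            r.auc,
            -r.metadata.get("G", 0),
            -r.metadata.get("F", 0),
        ),
    )


def results_to_frame(results: list[EvalResult]) -> pd.DataFrame:
    """Flatten results into the tables layout: approach, grouping, F, G,
    accuracy, ci, auc, sensitivity, specificity."""
    df = pd.DataFrame([r.as_row() for r in results])
    lead = [
        c
        for c in (
            "approach", "mode", "test_corpus", "grouping", "level", "F", "G",
            "accuracy", "ci_halfwidth", "auc", "sensitivity", "specificity",
        )
        if c in df.columns
    ]
    return df[lead + [c for c in df.columns if c not in lead]]
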