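"""Shared in-memory containers for utterance-level feature corpora.

A :class:`CorpusStore` is the unit the evaluation pipeline consumes: a flat
list of utterances, each carrying its feature matrix, its phone-level
alignment (when available) and speaker/class provenance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PD = "PD"
CTRL = "Ctrl"
CLASS_LABELS = (PD, CTRL)


@dataclass
class FrameMatrix:
    """Per-utterance feature vectors (N frames x D) with frame timing.

    ``frame_times`` are frame-centre times in seconds; they are what the
    grouping module tests against alignment intervals.
    """

    values: np.ndarray
    frame_times: np.ndarray
    utterance_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (N x D) array")
        if self.frame_times.shape != (self.values.shape[0],):
            raise ValueError("frame_times length must equal the frame count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class UtteranceRecord:
    """One utterance with provenance; ``segments`` is None when no alignment
    exists (then only ungrouped processing is possible)."""

    utterance_id: str
    speaker_id: str
    label: str                      # PD or Ctrl
    features: FrameMatrix
    segments: list | None = None    # list[AlignmentSegment]
    corpus_id: str = ""
    task_id: str = ""


@dataclass
class CorpusStore:
    """A corpus as consumed by training/adaptation/testing."""

    utterances: list[UtteranceRecord] = field(default_factory=list)
    corpus_id: str = ""

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self):
        return iter(self.utterances)

    def speakers(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self.utterances:
            seen.setdefault(u.speaker_id, None)
        return list(seen)

    def speaker_labels(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for u in self.utterances:
            prev = out.setdefault(u.speaker_id, u.label)
            if prev != u.label:
                raise ValueError(f"speaker {u.speaker_id} has inconsistent class labels")
        return out

    def subset_speakers(self, speaker_ids: Iterable[str]) -> "CorpusStore":
        keep = set(speaker_ids)
        return CorpusStore(
            [u for u in self.utterances if u.speaker_id in keep], self.corpus_id
        )

    def pooled_frames(self, label: str | None = None) -> np.ndarray:
        mats = [
            u.features.values
            for u in self.utterances
            if (label is None or u.label == label) and u.features.n_frames > 0
        ]
        if not mats:
            dim = self.utterances[0].features.dim if self.utterances else 0
            return np.empty((0, dim))
        return np.vstack(mats)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "utterance_id": u.utterance_id,
                    "speaker_id": u.speaker_id,
                    "class": u.label,
                    "corpus_id": u.corpus_id,
                    "task_id": u.task_id,
                    "n_frames": u.features.n_frames,
                }
                for u in self.utterances
            ]
        )


def merge_stores(stores: Sequence[CorpusStore], corpus_id: str = "") -> CorpusStore:
    """Pool several corpora (cross-corpora adaptation); speaker ids are
    prefixed with their corpus id to keep them globally unique."""
    merged: list[UtteranceRecord] = []
    for s in stores:
        for u in s.utterances:
            prefix = f"{s.corpus_id}:" if s.corpus_id else ""
            merged.append(
                replace(
                    u,
                    speaker_id=prefix + u.speaker_id,
                    utterance_id=prefix + u.utterance_id,
                )
            )
    return CorpusStore(merged, corpus_id)
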