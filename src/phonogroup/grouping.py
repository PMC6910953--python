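"""Phonemic grouping: phone-level alignments -> manner classes -> frame masks.

The grouping step is the core trick of the detection scheme: given a
forced-alignment of an utterance into phone intervals, select only the
feature frames whose centre falls inside intervals of one manner of
articulation (plosive, fricative, affricate, liquid, nasal or vowel).
Silence and anything unmapped fall into ``other`` so that the manner
classes plus ``other`` always partition the frames of an utterance.

Frame-to-segment rule: a frame belongs to the segment whose half-open
interval [start, end) contains its centre time.  This is the only
unambiguous convention for 50 %-overlapped frames, where boundary frames
straddle two phones.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .store import CorpusStore, FrameMatrix, UtteranceRecord

logger = logging.getLogger(__name__)

# tolerance used when testing a frame centre against an interval edge; it
# shifts both edges identically so the partition property is preserved
_EDGE_EPS = 1e-9


class MannerClass(str, Enum):
    AFFRICATE = "affricate"
    FRICATIVE = "fricative"
    LIQUID = "liquid"
    NASAL = "nasal"
    PLOSIVE = "plosive"
    VOWEL = "vowel"
    OTHER = "other"


#: the five manner classes a grouping experiment can target
SPEECH_CLASSES = (
    MannerClass.AFFRICATE,
    MannerClass.FRICATIVE,
    MannerClass.LIQUID,
    MannerClass.NASAL,
    MannerClass.PLOSIVE,
    MannerClass.VOWEL,
)

# Default Spanish allophone -> manner table (Quilis-style categorisation).
# Spirantized approximants [β ð ɣ] are mapped by their surface manner
# (fricative), not their canonical phoneme (plosive); glides [j w] pattern
# with vowels.  Both choices are overridable via a custom MannerMap.
_DEFAULT_TABLE: dict[str, MannerClass] = {
    **{p: MannerClass.PLOSIVE for p in ("p", "t", "k", "b", "d", "g")},
    **{
        p: MannerClass.FRICATIVE
        for p in ("f", "θ", "s", "ʂ", "x", "ʝ", "β", "ð", "ɣ")
    },
    "tʃ": MannerClass.AFFRICATE,
    **{p: MannerClass.LIQUID for p in ("l", "ʎ", "ɾ", "r", "ř")},
    **{p: MannerClass.NASAL for p in ("m", "n", "ɲ", "ŋ")},
    **{p: MannerClass.VOWEL for p in ("a", "e", "i", "o", "u", "j", "w")},
    **{p: MannerClass.OTHER for p in ("sil", "sp", "spn", "pau", "")},
}


@dataclass
class MannerMap:
    """Phone-label -> manner-class mapping with an ``other`` fallback."""

    table: dict[str, MannerClass] = field(default_factory=lambda: dict(_DEFAULT_TABLE))
    provenance: str = "default Spanish manner-of-articulation table"

    def resolve(self, label: str) -> MannerClass:
        try:
            return self.table[label]
        except KeyError:
            logger.warning("unmapped phone label %r -> other", label)
            return MannerClass.OTHER

    @classmethod
    def from_csv(cls, path: str | Path) -> "MannerMap":
        table = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, cls_name = (x.strip() for x in line.split(",", 1))
            table[label] = MannerClass(cls_name)
        return cls(table, provenance=str(path))


def default_manner_map() -> MannerMap:
    return MannerMap()


@dataclass(frozen=True)
class AlignmentSegment:
    """A labelled phone interval, in seconds."""

    label: str
    start: float
    end: float
    manner: MannerClass

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


# ---------------------------------------------------------------------------
# alignment readers
# ---------------------------------------------------------------------------

def _check_sorted(segments: list[AlignmentSegment]) -> list[AlignmentSegment]:
    segments = sorted(segments, key=lambda s: s.start)
    for a, b in zip(segments, segments[1:]):
        if b.start < a.end - _EDGE_EPS:
            raise ValueError(
                f"overlapping intervals: [{a.start},{a.end}) and [{b.start},{b.end})"
            )
    return segments


def _read_textgrid(path: Path, manner_map: MannerMap) -> list[AlignmentSegment]:
    """Minimal long-format Praat TextGrid reader: first interval tier named
    'phones' (or the first interval tier if none is)."""
    text = path.read_text(encoding="utf-8")
    # split into tiers; each interval tier item contains xmin/xmax/text triples
    tiers: list[tuple[str, list[tuple[float, float, str]]]] = []
    current_name = None
    current: list[tuple[float, float, str]] = []
    is_interval = False
    pending: dict[str, float | str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("class ="):
            if current_name is not None:
                tiers.append((current_name, current))
            current_name, current, pending = None, [], {}
            is_interval = '"IntervalTier"' in line
        elif line.startswith("name =") and is_interval and current_name is None:
            current_name = line.split("=", 1)[1].strip().strip('"')
        elif is_interval and line.startswith("xmin =") and "intervals" not in pending:
            pending["xmin"] = float(line.split("=", 1)[1])
        elif is_interval and line.startswith("xmax ="):
            pending["xmax"] = float(line.split("=", 1)[1])
        elif is_interval and line.startswith("text ="):
            label = line.split("=", 1)[1].strip().strip('"')
            if "xmin" in pending and "xmax" in pending:
                current.append((float(pending["xmin"]), float(pending["xmax"]), label))
            pending = {}
    if current_name is not None:
        tiers.append((current_name, current))
    if not tiers:
        return []
    for name, intervals in tiers:
        if name == "phones":
            chosen = intervals
            break
    else:
        chosen = tiers[0][1]
    # the tier header's own xmin/xmax sneak in as the first parsed pair when
    # the tier has them before "intervals: size"; drop zero-length artefacts
    segs = [
        AlignmentSegment(lab, lo, hi, manner_map.resolve(lab))
        for lo, hi, lab in chosen
        if hi > lo
    ]
    return _check_sorted(segs)


def _read_ctm(path: Path, manner_map: MannerMap) -> list[AlignmentSegment]:
    """CTM lines: <utt> <channel> <start> <dur> <label>."""
    segs = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith(";;"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"malformed CTM line: {line!r}")
        start, dur, label = float(parts[2]), float(parts[3]), parts[4]
        segs.append(
            AlignmentSegment(label, start, start + dur, manner_map.resolve(label))
        )
    return _check_sorted(segs)


def read_alignment(
    path: str | Path, manner_map: MannerMap | None = None
) -> list[AlignmentSegment]:
    """Read a phone alignment file (Praat TextGrid or CTM) into sorted,
    non-overlapping :class:`AlignmentSegment` objects with manner labels.

    The format is chosen by extension (``.textgrid`` / ``.ctm``); anything
    else is sniffed by content.
    """
    path = Path(path)
    manner_map = manner_map or default_manner_map()
    suffix = path.suffix.lower()
    if suffix == ".textgrid":
        return _read_textgrid(path, manner_map)
    if suffix == ".ctm":
        return _read_ctm(path, manner_map)
    head = path.read_text(encoding="utf-8", errors="replace")[:256]
    if "TextGrid" in head or "IntervalTier" in head:
        return _read_textgrid(path, manner_map)
    return _read_ctm(path, manner_map)


# ---------------------------------------------------------------------------
# frame selection
# ---------------------------------------------------------------------------

def frame_mask(
    frames: FrameMatrix,
    segments: list[AlignmentSegment],
    target: MannerClass,
) -> np.ndarray:
    """Boolean mask of the frames whose centre lies in a ``target`` segment."""
    t = frames.frame_times
    mask = np.zeros(frames.n_frames, dtype=bool)
    for seg in segments:
        if seg.manner is target:
            mask |= (t >= seg.start - _EDGE_EPS) & (t < seg.end - _EDGE_EPS)
    return mask


def select_frames(
    frames: FrameMatrix,
    segments: list[AlignmentSegment],
    target: MannerClass,
) -> tuple[FrameMatrix, np.ndarray]:
    """Subset a FrameMatrix to one manner class.

    Returns the (possibly 0-row) subset, frame order preserved, together
    with the length-N boolean mask.
    """
    mask = frame_mask(frames, segments, target)
    subset = FrameMatrix(
        frames.values[mask], frames.frame_times[mask], frames.utterance_id
    )
    return subset, mask


def group_corpus(
    store: CorpusStore, target: MannerClass
) -> tuple[CorpusStore, dict[str, int]]:
    """Apply phonemic grouping to every utterance of a corpus.

    Utterances without an alignment are skipped (counted); utterances whose
    grouped frame set is empty are retained as 0-row matrices — the scoring
    stage decides what to do with them.
    """
    out: list[UtteranceRecord] = []
    stats = {"skipped_no_alignment": 0, "empty_after_grouping": 0}
    for u in store:
        if u.segments is None:
            stats["skipped_no_alignment"] += 1
            logger.warning("utterance %s has no alignment; skipped", u.utterance_id)
            continue
        subset, _ = select_frames(u.features, u.segments, target)
        if subset.n_frames == 0:
            stats["empty_after_grouping"] += 1
        out.append(
            UtteranceRecord(
                u.utterance_id,
                u.speaker_id,
                u.label,
                subset,
                segments=u.segments,
                corpus_id=u.corpus_id,
                task_id=u.task_id,
            )
        )
    return CorpusStore(out, store.corpus_id), stats
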