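"""Seeded synthetic two-class speech corpora with manner-class alignments.

The real corpora this framework was designed around (dysarthric-speech
recordings with forced alignments) are restricted, so the package ships a
generator that emulates their structure: per-speaker utterances built by
concatenating manner-class segments from a grammar, with a controllable
class-specific acoustic effect on selected manner classes — an idealised
analogue of spirantization (degraded plosive closures) and vowel-space
reduction in parkinsonian speech.

Two modes:

* ``feature`` (default acceptance surface): segments emit feature vectors
  directly from per-class diagonal Gaussians; the patient effect is an
  exact mean shift (in units of the emission standard deviation) and
  variance scaling on the targeted classes, so downstream claims can be
  checked against known ground truth without DSP variance.
* ``waveform``: segments are rendered as crude source-filter audio
  (formant-filtered pulse trains for vowels, shaped noise for fricatives,
  closure + burst for plosives, low-passed periodic for nasals/liquids) at
  16 kHz to exercise the Rasta-PLP front-end end to end.  The patient
  effect here is a qualitative spirantization analogue (noise-filled
  closures, attenuated bursts) and carries no quantitative contract.

One RNG stream per corpus, consumed in a fixed order: the seed fully
determines the output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import lfilter

from .grouping import AlignmentSegment, MannerClass
from .store import CLASS_LABELS, PD, CorpusStore, FrameMatrix, UtteranceRecord

#: representative phone label written into alignments for each manner class
MANNER_PHONE = {
    MannerClass.PLOSIVE: "p",
    MannerClass.VOWEL: "a",
    MannerClass.FRICATIVE: "s",
    MannerClass.NASAL: "n",
    MannerClass.LIQUID: "l",
    MannerClass.AFFRICATE: "tʃ",
    MannerClass.OTHER: "sil",
}

#: DDK-style "pa-ta-ka" material: plosive-vowel alternation
DDK_GRAMMAR: tuple = tuple(
    [(MannerClass.PLOSIVE, (0.030, 0.060)), (MannerClass.VOWEL, (0.080, 0.150))] * 6
)

#: read-sentence-like material containing all five speech manner classes
TDU_GRAMMAR: tuple = tuple(
    [
        (MannerClass.PLOSIVE, (0.030, 0.060)),
        (MannerClass.VOWEL, (0.080, 0.150)),
        (MannerClass.FRICATIVE, (0.060, 0.120)),
        (MannerClass.VOWEL, (0.080, 0.150)),
        (MannerClass.NASAL, (0.050, 0.100)),
        (MannerClass.VOWEL, (0.080, 0.150)),
        (MannerClass.LIQUID, (0.040, 0.090)),
        (MannerClass.VOWEL, (0.080, 0.150)),
    ]
    * 2
)


@dataclass(frozen=True)
class ClassEffect:
    """Patient-class perturbation of one manner class: mean shift in units
    of the emission std, and a multiplicative variance scale."""

    mean_shift: float = 0.0
    var_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.var_scale <= 0:
            raise ValueError("variance scale must be positive")


def default_emissions(dim: int) -> dict[MannerClass, tuple[np.ndarray, np.ndarray]]:
    """Fixed per-manner-class emission parameters (mean, std).

    Class means are drawn once from a dedicated fixed-seed stream (so they
    are constants of the package, independent of the corpus seed) with unit
    emission std — acoustically distinct but overlapping classes.
    """
    rng = np.random.default_rng(20160901)
    out = {}
    for m in MannerClass:
        out[m] = (rng.normal(0.0, 1.0, size=dim), np.ones(dim))
    return out


@dataclass
class SimSpec:
    """Full description of a synthetic corpus; the seed determines it."""

    n_speakers_per_class: int = 20
    utterances_per_speaker: int = 4
    segment_grammar: tuple = TDU_GRAMMAR
    class_effect: dict = field(default_factory=dict)  # MannerClass -> ClassEffect
    n_features: int = 30
    speaker_sigma: float = 0.3   # per-speaker random offset std (feature mode)
    seed: int = 0
    mode: str = "feature"        # or "waveform"
    sample_rate: int = 16000
    frame_shift: float = 0.0075
    frame_length: float = 0.015
    corpus_id: str = "sim"
    task_id: str = "TDU"

    def __post_init__(self) -> None:
        if self.n_speakers_per_class < 1 or self.utterances_per_speaker < 1:
            raise ValueError("speaker and utterance counts must be positive")
        if not self.segment_grammar:
            raise ValueError("segment grammar must not be empty")
        for manner, (lo, hi) in self.segment_grammar:
            if not (0 < lo <= hi):
                raise ValueError(f"invalid duration range ({lo}, {hi}) for {manner}")
        if self.mode not in ("feature", "waveform"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "waveform" and self.sample_rate != 16000:
            raise ValueError("waveform mode is fixed at 16 kHz")
        self.class_effect = {
            MannerClass(k): (v if isinstance(v, ClassEffect) else ClassEffect(*v))
            for k, v in self.class_effect.items()
        }


@dataclass
class SimUtterance:
    utterance_id: str
    speaker_id: str
    label: str
    segments: list[AlignmentSegment]
    features: FrameMatrix | None = None
    waveform: np.ndarray | None = None


@dataclass
class SimCorpus:
    spec: SimSpec
    utterances: list[SimUtterance]
    emissions: dict

    def to_store(self) -> CorpusStore:
        """Feature-mode corpus as a ready-to-evaluate CorpusStore."""
        if self.spec.mode != "feature":
            raise ValueError(
                "waveform corpora go through the features module first"
            )
        return CorpusStore(
            [
                UtteranceRecord(
                    u.utterance_id,
                    u.speaker_id,
                    u.label,
                    u.features,
                    segments=u.segments,
                    corpus_id=self.spec.corpus_id,
                    task_id=self.spec.task_id,
                )
                for u in self.utterances
            ],
            self.spec.corpus_id,
        )

    def ground_truth_json(self) -> str:
        return json.dumps(
            {
                "seed": self.spec.seed,
                "mode": self.spec.mode,
                "n_features": self.spec.n_features,
                "class_effect": {
                    m.value: {"mean_shift": e.mean_shift, "var_scale": e.var_scale}
                    for m, e in self.spec.class_effect.items()
                },
                "emissions": {
                    m.value: {"mean": mu.tolist(), "std": sd.tolist()}
                    for m, (mu, sd) in self.emissions.items()
                },
            },
            indent=1,
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _segment_plan(
    spec: SimSpec, rng: np.random.Generator
) -> list[tuple[MannerClass, float]]:
    return [
        (manner, float(rng.uniform(lo, hi))) for manner, (lo, hi) in spec.segment_grammar
    ]


def _feature_utterance(
    spec: SimSpec,
    rng: np.random.Generator,
    emissions: dict,
    label: str,
    speaker_offset: np.ndarray,
    utt_id: str,
) -> SimUtterance:
    hop, flen = spec.frame_shift, spec.frame_length
    plan = _segment_plan(spec, rng)
    counts = [max(1, int(round(dur / hop))) for _, dur in plan]
    n_total = sum(counts)
    frame_times = np.arange(n_total) * hop + flen / 2
    # boundaries halfway between adjacent frame centres; outer edges extended
    values = np.empty((n_total, spec.n_features))
    segments: list[AlignmentSegment] = []
    pos = 0
    for (manner, _), cnt in zip(plan, counts):
        mu, sd = emissions[manner]
        mu = mu + speaker_offset
        sd = np.array(sd, copy=True)
        if label == PD and manner in spec.class_effect:
            eff = spec.class_effect[manner]
            mu = mu + eff.mean_shift * emissions[manner][1]
            sd = sd * np.sqrt(eff.var_scale)
        values[pos : pos + cnt] = rng.normal(mu, sd, size=(cnt, spec.n_features))
        start = 0.0 if pos == 0 else (pos - 0.5) * hop + flen / 2
        endpos = pos + cnt
        end = (
            (n_total - 1) * hop + flen
            if endpos == n_total
            else (endpos - 0.5) * hop + flen / 2
        )
        segments.append(
            AlignmentSegment(MANNER_PHONE[manner], start, end, manner)
        )
        pos = endpos
    feats = FrameMatrix(values, frame_times, utt_id)
    return SimUtterance(utt_id, "", label, segments, features=feats)


# -- waveform rendering ------------------------------------------------------

def _resonator(x: np.ndarray, freq: float, bw: float, sr: int) -> np.ndarray:
    r = np.exp(-np.pi * bw / sr)
    theta = 2.0 * np.pi * freq / sr
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    return lfilter([1.0 - r], a, x)


def _pulse_train(n: int, f0: float, sr: int) -> np.ndarray:
    x = np.zeros(n)
    period = max(1, int(round(sr / f0)))
    x[::period] = 1.0
    return x


def _render_segment(
    manner: MannerClass,
    n: int,
    sr: int,
    rng: np.random.Generator,
    spirantize: float,
) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, n)
    if manner is MannerClass.VOWEL:
        src = _pulse_train(n, 120.0, sr)
        y = _resonator(_resonator(src, 700.0, 90.0, sr), 1200.0, 110.0, sr)
    elif manner is MannerClass.FRICATIVE:
        y = _resonator(noise, 4500.0, 2000.0, sr)
    elif manner is MannerClass.NASAL:
        y = _resonator(_pulse_train(n, 120.0, sr), 300.0, 80.0, sr)
    elif manner is MannerClass.LIQUID:
        y = _resonator(_pulse_train(n, 120.0, sr), 1000.0, 300.0, sr)
    elif manner in (MannerClass.PLOSIVE, MannerClass.AFFRICATE):
        closure = int(0.7 * n) if manner is MannerClass.PLOSIVE else int(0.4 * n)
        y = np.zeros(n)
        # spirantization analogue: frication leaks into the closure and the
        # burst loses energy as the effect grows
        leak = min(1.0, max(0.0, spirantize))
        y[:closure] = 0.02 * leak * _resonator(noise[:closure], 3500.0, 1500.0, sr)
        burst = _resonator(noise[closure:], 3000.0, 2500.0, sr)
        env = np.exp(-np.arange(n - closure) / (0.004 * sr))
        y[closure:] = (1.0 - 0.5 * leak) * burst * env
    else:  # silence / other
        y = 0.001 * noise
    peak = np.max(np.abs(y))
    if peak > 0 and manner is not MannerClass.OTHER:
        y = 0.3 * y / peak
    return y + 0.001 * rng.normal(0.0, 1.0, n)


def _waveform_utterance(
    spec: SimSpec, rng: np.random.Generator, label: str, utt_id: str
) -> SimUtterance:
    sr = spec.sample_rate
    plan = _segment_plan(spec, rng)
    counts = [max(1, int(round(dur * sr))) for _, dur in plan]
    segments: list[AlignmentSegment] = []
    chunks = []
    pos = 0
    for (manner, _), cnt in zip(plan, counts):
        eff = spec.class_effect.get(manner)
        spir = eff.mean_shift if (eff is not None and label == PD) else 0.0
        chunks.append(_render_segment(manner, cnt, sr, rng, spir))
        segments.append(
            AlignmentSegment(
                MANNER_PHONE[manner], pos / sr, (pos + cnt) / sr, manner
            )
        )
        pos += cnt
    return SimUtterance(utt_id, "", label, segments, waveform=np.concatenate(chunks))


def generate_corpus(spec: SimSpec) -> SimCorpus:
    """Generate a seeded two-class corpus according to ``spec``.

    Deterministic: the single RNG stream is consumed in a fixed order
    (speakers by class then index, utterances in order, segments in order).
    """
    rng = np.random.default_rng(spec.seed)
    emissions = default_emissions(spec.n_features)
    utterances: list[SimUtterance] = []
    for label in CLASS_LABELS:
        for s in range(spec.n_speakers_per_class):
            speaker_id = f"{spec.corpus_id}-{label}-{s:03d}"
            offset = rng.normal(0.0, spec.speaker_sigma, spec.n_features)
            for u in range(spec.utterances_per_speaker):
                utt_id = f"{speaker_id}-u{u:02d}"
                if spec.mode == "feature":
                    utt = _feature_utterance(
                        spec, rng, emissions, label, offset, utt_id
                    )
                else:
                    utt = _waveform_utterance(spec, rng, label, utt_id)
                utt.speaker_id = speaker_id
                utterances.append(utt)
    return SimCorpus(spec, utterances, emissions)


# ---------------------------------------------------------------------------
# serialisation: alignments, audio, manifest
# ---------------------------------------------------------------------------

def _textgrid_text(segments: list[AlignmentSegment]) -> str:
    xmax = segments[-1].end if segments else 0.0
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax:.9f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        '        name = "phones"',
        "        xmin = 0",
        f"        xmax = {xmax:.9f}",
        f"        intervals: size = {len(segments)}",
    ]
    for i, seg in enumerate(segments, 1):
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {seg.start:.9f}",
            f"            xmax = {seg.end:.9f}",
            f'            text = "{seg.label}"',
        ]
    return "\n".join(lines) + "\n"


def _ctm_text(utt_id: str, segments: list[AlignmentSegment]) -> str:
    return "".join(
        f"{utt_id} 1 {seg.start:.9f} {seg.end - seg.start:.9f} {seg.label}\n"
        for seg in segments
    )


def write_alignments(
    corpus: SimCorpus, fmt: str, out_dir: str | Path
) -> list[Path]:
    """Write one alignment file per utterance in TextGrid or CTM format."""
    fmt = fmt.lower()
    if fmt not in ("textgrid", "ctm"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for u in corpus.utterances:
        if fmt == "textgrid":
            p = out_dir / f"{u.utterance_id}.TextGrid"
            p.write_text(_textgrid_text(u.segments), encoding="utf-8")
        else:
            p = out_dir / f"{u.utterance_id}.ctm"
            p.write_text(_ctm_text(u.utterance_id, u.segments), encoding="utf-8")
        paths.append(p)
    return paths


def write_audio(corpus: SimCorpus, out_dir: str | Path) -> list[Path]:
    """Write waveform-mode utterances as 16-bit PCM WAV files."""
    if corpus.spec.mode != "waveform":
        raise ValueError("write_audio requires a waveform-mode corpus")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for u in corpus.utterances:
        p = out_dir / f"{u.utterance_id}.wav"
        x = u.waveform / max(1e-9, np.max(np.abs(u.waveform)))
        wavfile.write(str(p), corpus.spec.sample_rate, (x * 32767).astype(np.int16))
        paths.append(p)
    return paths


def write_manifest(corpus: SimCorpus, path: str | Path) -> None:
    """Speaker manifest CSV: speaker_id, class, utterance_id, path."""
    lines = ["speaker_id,class,utterance_id,path"]
    for u in corpus.utterances:
        stem = f"{u.utterance_id}.wav" if corpus.spec.mode == "waveform" else ""
        lines.append(f"{u.speaker_id},{u.label},{u.utterance_id},{stem}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
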