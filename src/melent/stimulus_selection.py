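"""Entropy-driven probe-tone stimulus selection.

A two-stage procedure selects melodic contexts whose next-note predictions
are extreme in entropy:

1. Every note of each stimulus corpus is scored with the entropy of the
   model's full-alphabet predictive distribution at that position ("37-tone
   entropy" when the alphabet is a 37-pitch chromatic span).  The highest- and
   lowest-scoring notes become candidate targets, each wrapped in a melodic
   context: the shortest phrase-initial prefix containing at least one
   complete phrase, at least eight notes and at least four distinct pitches.

2. Each candidate receives nine chromatically consecutive probe tones centred
   on the context's median pitch (shifted minimally to include the true
   continuation).  Candidates are re-scored by the entropy of the predictive
   distribution renormalized over their nine probes ("9-tone entropy"), with
   the key re-estimated from the context itself, and the most extreme
   candidates per (style x entropy-class) cell are retained, skipping contexts
   that overlap an already chosen one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expectation_model import (
    ModelConfig,
    NGramStore,
    build_alphabet,
    melody_key,
    sequence_predictions,
)
from .info_measures import PredictiveDistribution, entropy, renormalize_subset
from .key_finding import estimate_key
from .melody_io import Corpus, Melody, MelodyValidationError, NoteEvent

__all__ = [
    "StimulusContext",
    "StimulusSet",
    "Rejection",
    "score_corpus_notes",
    "select_candidate_notes",
    "extract_candidate_context",
    "assign_probe_tones",
    "select_stimulus_set",
]

HIGH, LOW = "high", "low"


@dataclass
class StimulusContext:
    """A melodic prefix, its target continuation, and probe-tone assignment."""

    melody_prefix: Melody
    target_pitch: int
    style: str
    entropy_class: str
    melody_id: str
    context_start: int
    target_index: int
    target_onset: float
    target_duration: float
    probe_pitches: Optional[tuple[int, ...]] = None
    entropy_37: Optional[float] = None
    entropy_9: Optional[float] = None
    key_used: Optional[tuple] = None  # (Key, "notated" | "estimated")

    def __post_init__(self) -> None:
        if self.entropy_class not in (HIGH, LOW):
            raise ValueError(f"entropy_class must be high/low, got "
                             f"{self.entropy_class!r}")
        if self.probe_pitches is not None:
            probes = tuple(self.probe_pitches)
            if len(probes) != 9 or any(
                    b - a != 1 for a, b in zip(probes, probes[1:])):
                raise ValueError("probe_pitches must be 9 chromatically "
                                 "consecutive pitches")
            if self.target_pitch not in probes:
                raise ValueError("target pitch must be among the probes")
            self.probe_pitches = probes

    @property
    def label(self) -> str:
        return f"{self.melody_id}@{self.target_index}"

    def overlaps(self, other: "StimulusContext") -> bool:
        """True when the two contexts share any note span of one melody."""
        if self.melody_id != other.melody_id:
            return False
        return not (self.target_index < other.context_start
                    or other.target_index < self.context_start)


@dataclass(frozen=True)
class Rejection:
    """A candidate note for which no qualifying context prefix exists."""

    melody_id: str
    note_index: int
    reason: str


@dataclass
class StimulusSet:
    stimuli: list[StimulusContext]
    config_label: str = ""

    def __len__(self) -> int:
        return len(self.stimuli)

    def cell(self, style: str, entropy_class: str) -> list[StimulusContext]:
        return [s for s in self.stimuli
                if s.style == style and s.entropy_class == entropy_class]

    def to_json(self) -> dict:
        payload = []
        for s in self.stimuli:
            key, key_source = s.key_used if s.key_used else (None, None)
            payload.append({
                "melody_id": s.melody_id,
                "style": s.style,
                "entropy_class": s.entropy_class,
                "context_start": s.context_start,
                "target_index": s.target_index,
                "target_pitch": s.target_pitch,
                "target_onset": s.target_onset,
                "target_duration": s.target_duration,
                "probe_pitches": list(s.probe_pitches or ()),
                "entropy_37": s.entropy_37,
                "entropy_9": s.entropy_9,
                "key": None if key is None else
                       {"tonic": key.tonic, "mode": key.mode,
                        "source": key_source},
                "prefix_notes": [
                    [e.pitch, e.onset, e.duration, e.phrase_start]
                    for e in s.melody_prefix.events
                ],
            })
        return {"format": "melent-stimulus-set", "version": 1,
                "config": self.config_label, "stimuli": payload}

    @classmethod
    def from_json(cls, payload: dict) -> "StimulusSet":
        from .viewpoints import Key

        stimuli = []
        for entry in payload["stimuli"]:
            events = tuple(
                NoteEvent(pitch=p, onset=o, duration=d, phrase_start=ph)
                for p, o, d, ph in entry["prefix_notes"]
            )
            prefix = Melody(id=f"{entry['melody_id']}-ctx", events=events,
                            style=entry["style"])
            key_used = None
            if entry.get("key"):
                key_used = (Key(entry["key"]["tonic"], entry["key"]["mode"]),
                            entry["key"]["source"])
            stimuli.append(StimulusContext(
                melody_prefix=prefix,
                target_pitch=entry["target_pitch"],
                style=entry["style"],
                entropy_class=entry["entropy_class"],
                melody_id=entry["melody_id"],
                context_start=entry["context_start"],
                target_index=entry["target_index"],
                target_onset=entry["target_onset"],
                target_duration=entry["target_duration"],
                probe_pitches=tuple(entry["probe_pitches"]) or None,
                entropy_37=entry.get("entropy_37"),
                entropy_9=entry.get("entropy_9"),
                key_used=key_used,
            ))
        return cls(stimuli=stimuli, config_label=payload.get("config", ""))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1),
                              encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "StimulusSet":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# stage 1: per-note entropy scoring and candidate extraction
# ---------------------------------------------------------------------------


def score_corpus_notes(corpus: Corpus, ltm: Optional[NGramStore],
                       config: ModelConfig,
                       alphabet: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Entropy of the full-alphabet predictive distribution at every note.

    Returns a tidy table (melody_id, note_index, entropy) covering each note
    of each melody, computed with the melody's stored (notated) key.
    """
    if alphabet is None:
        alphabet = build_alphabet(corpus, policy="chromatic_span")
    rows = []
    for melody in corpus.melodies:
        preds = sequence_predictions(melody, ltm, melody_key(melody), config,
                                     alphabet)
        for i, d in enumerate(preds):
            rows.append((melody.id, i, entropy(d)))
    return pd.DataFrame(rows, columns=["melody_id", "note_index", "entropy"])


def select_candidate_notes(scores: pd.DataFrame,
                           k_per_extreme: int) -> pd.DataFrame:
    """The k highest- and k lowest-entropy notes of one corpus's score table.

    Ties break by (melody_id, note_index) ascending.  Returns the selected
    rows with an ``entropy_class`` column.
    """
    if scores.empty:
        raise MelodyValidationError("score table is empty")
    if 2 * k_per_extreme > len(scores):
        raise MelodyValidationError(
            f"cannot take 2x{k_per_extreme} extremes from {len(scores)} notes")
    hi = scores.sort_values(
        ["entropy", "melody_id", "note_index"],
        ascending=[False, True, True], kind="mergesort").head(k_per_extreme)
    lo = scores.sort_values(
        ["entropy", "melody_id", "note_index"],
        ascending=[True, True, True], kind="mergesort").head(k_per_extreme)
    hi = hi.assign(entropy_class=HIGH)
    lo = lo.assign(entropy_class=LOW)
    return pd.concat([hi, lo], ignore_index=True)


# context prefix constraints
MIN_CONTEXT_NOTES = 8
MIN_DISTINCT_PITCHES = 4


def extract_candidate_context(corpus: Corpus, melody_id: str, note_index: int,
                              entropy_class: str,
                              entropy_37: Optional[float] = None
                              ) -> StimulusContext | Rejection:
    """Wrap a candidate target note in a qualifying melodic context.

    The prefix runs from a phrase-starting note up to (excluding) the target
    and must contain at least one complete phrase, at least eight notes, and
    at least four distinct pitches.  The shortest qualifying prefix is chosen
    (extending back one phrase boundary at a time); when none qualifies a
    :class:`Rejection` records why.
    """
    melody = next((m for m in corpus.melodies if m.id == melody_id), None)
    if melody is None:
        raise MelodyValidationError(f"melody {melody_id!r} not in corpus")
    if not 0 <= note_index < len(melody):
        raise MelodyValidationError(f"note index {note_index} out of range")

    phrase_starts = [i for i, e in enumerate(melody.events) if e.phrase_start]
    starts_before = [i for i in phrase_starts if i < note_index]
    if not starts_before:
        return Rejection(melody_id, note_index, "target starts the melody")

    reason = "no qualifying prefix"
    for start in reversed(starts_before):  # shortest prefix first
        length = note_index - start
        if length < MIN_CONTEXT_NOTES:
            reason = f"fewer than {MIN_CONTEXT_NOTES} notes available"
            continue
        # a phrase begun at `start` is complete within the prefix only if a
        # later phrase boundary occurs at or before the target
        if not any(start < b <= note_index for b in phrase_starts):
            reason = "no complete phrase before the target"
            continue
        prefix_events = melody.events[start:note_index]
        if len({e.pitch for e in prefix_events}) < MIN_DISTINCT_PITCHES:
            reason = f"fewer than {MIN_DISTINCT_PITCHES} distinct pitches"
            continue
        target = melody.events[note_index]
        return StimulusContext(
            melody_prefix=melody.prefix(note_index, start=start),
            target_pitch=target.pitch,
            style=melody.style,
            entropy_class=entropy_class,
            melody_id=melody_id,
            context_start=start,
            target_index=note_index,
            target_onset=target.onset,
            target_duration=target.duration,
            entropy_37=entropy_37,
        )
    return Rejection(melody_id, note_index, reason)


# ---------------------------------------------------------------------------
# stage 2: probe assignment and final selection
# ---------------------------------------------------------------------------


def _median_pitch(pitches: Sequence[int]) -> int:
    """Median pitch, rounding the even-length midpoint half down."""
    ordered = sorted(pitches)
    m = len(ordered)
    if m % 2 == 1:
        return ordered[m // 2]
    mid = (ordered[m // 2 - 1] + ordered[m // 2]) / 2.0
    return math.ceil(mid - 0.5)


def assign_probe_tones(prefix: Melody, target_pitch: int,
                       pitch_bounds: Optional[tuple[int, int]] = None
                       ) -> tuple[int, ...]:
    """Nine chromatically consecutive probe pitches for a context.

    The window is centred on the context's median pitch and shifted by the
    minimal number of semitones needed to include the true continuation, so
    highly expected continuations are never excluded from the probe set.
    ``pitch_bounds`` (inclusive), when given, additionally keeps the window
    inside the model's pitch alphabet; the target always stays included.
    """
    if len(prefix) == 0:
        raise MelodyValidationError("context prefix is empty")
    m = _median_pitch(prefix.pitches)
    lo, hi = m - 4, m + 4
    if target_pitch < lo:
        shift = target_pitch - lo
    elif target_pitch > hi:
        shift = target_pitch - hi
    else:
        shift = 0
    lo, hi = lo + shift, hi + shift
    if pitch_bounds is not None:
        b_lo, b_hi = pitch_bounds
        if not b_lo <= target_pitch <= b_hi:
            raise MelodyValidationError(
                f"target pitch {target_pitch} outside alphabet bounds "
                f"{b_lo}-{b_hi}")
        if b_hi - b_lo + 1 < 9:
            raise MelodyValidationError("alphabet narrower than the probe "
                                        "window")
        if lo < b_lo:
            lo, hi = b_lo, b_lo + 8
        elif hi > b_hi:
            lo, hi = b_hi - 8, b_hi
    return tuple(range(lo, hi + 1))


def target_distribution(stim: StimulusContext, ltm: Optional[NGramStore],
                        key, config: ModelConfig,
                        alphabet: Sequence[int]) -> PredictiveDistribution:
    """Predictive distribution for a stimulus's target position.

    Rebuilds the context melody with the target appended so the STM (when
    active) has learned from exactly the notes the listener heard.
    """
    events = stim.melody_prefix.events + (
        NoteEvent(pitch=stim.target_pitch, onset=stim.target_onset,
                  duration=stim.target_duration),
    )
    melody = Melody(id=stim.label, events=events, style=stim.style)
    preds = sequence_predictions(melody, ltm, key, config, alphabet)
    return preds[-1]


def select_stimulus_set(candidates: Sequence[StimulusContext],
                        ltm: Optional[NGramStore], config: ModelConfig,
                        per_cell: int,
                        alphabet: Sequence[int]) -> StimulusSet:
    """Final stimulus selection by 9-tone entropy extremes.

    Each candidate gets probe tones, a key re-estimated from its own context
    (profile correlation), and a 9-tone entropy: the entropy of its predictive
    distribution renormalized over the probes.  Per (style x entropy-class)
    cell the ``per_cell`` most extreme candidates are kept — highest 9-tone
    entropy for high cells, lowest for low cells — skipping candidates that
    overlap an already selected context of the same melody.
    """
    bounds = (min(alphabet), max(alphabet))
    scored: list[StimulusContext] = []
    for stim in candidates:
        key = estimate_key(stim.melody_prefix)
        probes = assign_probe_tones(stim.melody_prefix, stim.target_pitch,
                                    pitch_bounds=bounds)
        d = target_distribution(stim, ltm, key, config, alphabet)
        d9 = renormalize_subset(d, probes)
        stim.probe_pitches = probes
        stim.key_used = (key, "estimated")
        stim.entropy_37 = entropy(d)
        stim.entropy_9 = entropy(d9)
        scored.append(stim)

    selected: list[StimulusContext] = []
    styles = sorted({s.style for s in scored})
    for style in styles:
        for entropy_class in (HIGH, LOW):
            pool = [s for s in scored
                    if s.style == style and s.entropy_class == entropy_class]
            pool.sort(key=lambda s: (
                -s.entropy_9 if entropy_class == HIGH else s.entropy_9,
                s.melody_id, s.target_index))
            chosen: list[StimulusContext] = []
            for stim in pool:
                if any(stim.overlaps(prev) for prev in chosen + selected):
                    continue
                chosen.append(stim)
                if len(chosen) == per_cell:
                    break
            if len(chosen) < per_cell:
                raise MelodyValidationError(
                    f"cell ({style}, {entropy_class}): only {len(chosen)} "
                    f"non-overlapping candidates for per_cell={per_cell}")
            selected.extend(chosen)
    return StimulusSet(stimuli=selected, config_label=config.label())
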