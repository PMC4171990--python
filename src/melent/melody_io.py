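"""Symbolic melody I/O and the canonical in-memory representation.

Melodies are ordered sequences of monophonic note events with pitch given as a
chromatic MIDI number (middle C = 60), and time in abstract beat units
(quarter note = 1.0).  Tempo is a presentation concern and is not represented.

Three external formats are supported:

* a plain-text note table (UTF-8 CSV with columns
  ``pitch,onset,duration,phrase_start``), the diff-able fixture format;
* Standard MIDI Files, type 0 or 1, restricted to monophonic content
  (a minimal reader/writer is implemented here);
* a corpus manifest: a JSON file listing melody files with style labels.
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "NoteEvent",
    "Melody",
    "Corpus",
    "MelodyFormatError",
    "MelodyValidationError",
    "read_note_table",
    "write_note_table",
    "read_midi_melody",
    "write_midi_melody",
    "infer_phrases",
    "read_corpus_manifest",
    "write_corpus_manifest",
    "pitch_name",
]

#: Default permissible chromatic pitch range (A0..C8).
PITCH_RANGE = (21, 108)

_NOTE_NAMES = ["C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B"]


class MelodyFormatError(ValueError):
    """A file does not conform to the expected external format."""


class MelodyValidationError(ValueError):
    """Parsed content violates a melody invariant."""


@dataclass(frozen=True)
class NoteEvent:
    """A single monophonic note: pitch, onset and duration in beats."""

    pitch: int
    onset: float
    duration: float
    phrase_start: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise MelodyValidationError(
                f"note duration must be positive, got {self.duration}"
            )

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Melody:
    """An ordered monophonic note sequence with provenance metadata."""

    id: str
    events: tuple[NoteEvent, ...]
    style: str = "synthetic"
    key: "object | None" = None  # viewpoints.Key; kept loose to avoid a cycle
    source: str = ""

    def __post_init__(self) -> None:
        if not self.events:
            raise MelodyValidationError(f"melody {self.id!r} has no events")
        object.__setattr__(self, "events", tuple(self.events))
        onsets = [e.onset for e in self.events]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise MelodyValidationError(f"melody {self.id!r}: onsets decrease")
        lo, hi = PITCH_RANGE
        for i, e in enumerate(self.events):
            if not (lo <= e.pitch <= hi):
                raise MelodyValidationError(
                    f"melody {self.id!r}: pitch {e.pitch} at index {i} outside "
                    f"range {lo}-{hi}"
                )
        if not self.events[0].phrase_start:
            # first event always opens a phrase
            first = replace(self.events[0], phrase_start=True)
            object.__setattr__(self, "events", (first,) + self.events[1:])

    def __len__(self) -> int:
        return len(self.events)

    @property
    def pitches(self) -> tuple[int, ...]:
        return tuple(e.pitch for e in self.events)

    def prefix(self, n: int, start: int = 0) -> "Melody":
        """Sub-melody of events[start:n] (n exclusive), keeping metadata."""
        return Melody(
            id=f"{self.id}[{start}:{n}]",
            events=self.events[start:n],
            style=self.style,
            key=self.key,
            source=self.source,
        )


@dataclass
class Corpus:
    """A collection of melodies and the pitch alphabet they induce."""

    melodies: list[Melody]
    alphabet: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.melodies:
            raise MelodyValidationError("corpus is empty")
        derived = tuple(sorted({p for m in self.melodies for p in m.pitches}))
        if self.alphabet and tuple(self.alphabet) != derived:
            raise MelodyValidationError(
                "corpus alphabet does not match the union of melody pitches"
            )
        self.alphabet = derived

    def __len__(self) -> int:
        return len(self.melodies)

    @property
    def n_events(self) -> int:
        return sum(len(m) for m in self.melodies)

    @property
    def pitch_range(self) -> tuple[int, int]:
        return self.alphabet[0], self.alphabet[-1]


def pitch_name(pitch: int) -> str:
    """Scientific pitch name for a chromatic number (60 -> 'C4', 47 -> 'B2')."""
    return f"{_NOTE_NAMES[pitch % 12]}{pitch // 12 - 1}"


# ---------------------------------------------------------------------------
# note-table CSV
# ---------------------------------------------------------------------------

_COLUMNS = ("pitch", "onset", "duration", "phrase_start")
_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no"}


def _parse_bool(text: str, row: int) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise MelodyFormatError(f"row {row}: cannot parse boolean {text!r}")


def read_note_table(path: str | Path, melody_id: str | None = None,
                    style: str = "synthetic") -> Melody:
    """Read a melody from a CSV note table.

    Columns ``pitch,onset,duration,phrase_start`` are required; extra columns
    are ignored.  Row numbers in error messages are 1-based data rows.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise MelodyFormatError(
                f"{path}: missing column(s) {', '.join(missing)}"
            )
        events = []
        for i, row in enumerate(reader, start=1):
            try:
                dur = float(row["duration"])
                if dur <= 0:
                    raise MelodyValidationError(
                        f"{path}: non-positive duration at row {i}"
                    )
                events.append(
                    NoteEvent(
                        pitch=int(row["pitch"]),
                        onset=float(row["onset"]),
                        duration=dur,
                        phrase_start=_parse_bool(row["phrase_start"], i),
                    )
                )
            except (TypeError, KeyError) as exc:
                raise MelodyFormatError(f"{path}: malformed row {i}") from exc
    if not events:
        raise MelodyValidationError(f"{path}: table contains no notes")
    return Melody(id=melody_id or path.stem, events=tuple(events), style=style,
                  source=str(path))


def write_note_table(melody: Melody, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for e in melody.events:
            writer.writerow(
                [e.pitch, repr(e.onset), repr(e.duration),
                 "true" if e.phrase_start else "false"]
            )


# ---------------------------------------------------------------------------
# minimal Standard MIDI File support (type 0/1, monophonic)
# ---------------------------------------------------------------------------


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _encode_varlen(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def _parse_track(data: bytes) -> list[tuple[int, int, int, int]]:
    """Return (tick, kind, pitch, velocity) note events; kind 1=on, 0=off."""
    events = []
    pos, tick, running = 0, 0, 0
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            running = status
        else:
            status = running
        kind = status & 0xF0
        if kind in (0x80, 0x90):
            pitch, vel = data[pos], data[pos + 1]
            pos += 2
            if kind == 0x90 and vel > 0:
                events.append((tick, 1, pitch, vel))
            else:
                events.append((tick, 0, pitch, vel))
        elif kind in (0xA0, 0xB0, 0xE0):
            pos += 2
        elif kind in (0xC0, 0xD0):
            pos += 1
        elif status == 0xFF:  # meta
            pos += 1  # meta type
            length, pos = _read_varlen(data, pos)
            pos += length
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varlen(data, pos)
            pos += length
        else:
            raise MelodyFormatError(f"unsupported MIDI status byte {status:#x}")
    return events


def read_midi_melody(path: str | Path, track_policy: int | str = "first_notes",
                     phrase_gap: float = 1.0) -> Melody:
    """Read a monophonic melody from a type 0/1 Standard MIDI File.

    ``track_policy`` selects the track: an integer index, or ``"first_notes"``
    for the first track containing note events.  Onsets and durations are
    expressed in beats using the file's ticks-per-quarter resolution.  Phrase
    starts are inferred from silent gaps via :func:`infer_phrases`.

    Raises :class:`MelodyFormatError` if the selected track is polyphonic
    (overlapping notes) or the file is not a readable SMF.
    """
    path = Path(path)
    data = path.read_bytes()
    if data[:4] != b"MThd":
        raise MelodyFormatError(f"{path}: not a Standard MIDI File")
    header_len = struct.unpack(">I", data[4:8])[0]
    fmt, ntracks, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise MelodyFormatError(f"{path}: unsupported SMF type {fmt}")
    if division & 0x8000:
        raise MelodyFormatError(f"{path}: SMPTE time division unsupported")
    pos = 8 + header_len
    tracks = []
    for _ in range(ntracks):
        if data[pos:pos + 4] != b"MTrk":
            raise MelodyFormatError(f"{path}: malformed track chunk")
        length = struct.unpack(">I", data[pos + 4:pos + 8])[0]
        tracks.append(data[pos + 8:pos + 8 + length])
        pos += 8 + length

    parsed = [_parse_track(t) for t in tracks]
    if track_policy == "first_notes":
        candidates = [ev for ev in parsed if ev]
        if not candidates:
            raise MelodyValidationError(f"{path}: no note events in any track")
        note_events = candidates[0]
    else:
        note_events = parsed[int(track_policy)]

    events: list[NoteEvent] = []
    open_note: tuple[int, int] | None = None  # (tick, pitch)
    for tick, kind, pitch, _vel in note_events:
        if kind == 1:
            if open_note is not None:
                raise MelodyFormatError(
                    f"{path}: polyphonic content (overlapping notes) at tick "
                    f"{tick}"
                )
            open_note = (tick, pitch)
        else:
            if open_note is None or open_note[1] != pitch:
                raise MelodyFormatError(
                    f"{path}: unmatched note-off for pitch {pitch}"
                )
            start, _ = open_note
            events.append(
                NoteEvent(pitch=pitch, onset=start / division,
                          duration=(tick - start) / division)
            )
            open_note = None
    if open_note is not None:
        raise MelodyFormatError(f"{path}: note-on without note-off")
    if not events:
        raise MelodyValidationError(f"{path}: no notes")
    melody = Melody(id=path.stem, events=tuple(events), source=str(path))
    return infer_phrases(melody, gap_threshold=phrase_gap)


def write_midi_melody(melody: Melody, path: str | Path,
                      ticks_per_beat: int = 480, program: int = 0) -> None:
    """Write a melody as a single-track type-0 SMF."""
    path = Path(path)
    body = bytearray()
    body += _encode_varlen(0) + bytes([0xC0, program])
    last_tick = 0
    for e in melody.events:
        on = round(e.onset * ticks_per_beat)
        off = round(e.offset * ticks_per_beat)
        body += _encode_varlen(on - last_tick) + bytes([0x90, e.pitch, 64])
        body += _encode_varlen(off - on) + bytes([0x80, e.pitch, 0])
        last_tick = off
    body += _encode_varlen(0) + b"\xff\x2f\x00"  # end of track
    header = b"MThd" + struct.pack(">IHHH", 6, 0, 1, ticks_per_beat)
    track = b"MTrk" + struct.pack(">I", len(body)) + bytes(body)
    path.write_bytes(header + track)


# ---------------------------------------------------------------------------
# phrase inference
# ---------------------------------------------------------------------------


def infer_phrases(melody: Melody, gap_threshold: float = 1.0) -> Melody:
    """Mark phrase starts from silent gaps.

    The first event always starts a phrase; any event whose onset follows the
    previous event's offset by at least ``gap_threshold`` beats of silence
    starts a new phrase.  All other flags are cleared.
    """
    if gap_threshold <= 0:
        raise MelodyValidationError("gap_threshold must be positive")
    events = []
    for i, e in enumerate(melody.events):
        if i == 0:
            flag = True
        else:
            gap = e.onset - melody.events[i - 1].offset
            flag = gap >= gap_threshold
        events.append(replace(e, phrase_start=flag))
    return replace(melody, events=tuple(events))


# ---------------------------------------------------------------------------
# corpus manifests
# ---------------------------------------------------------------------------


def read_corpus_manifest(path: str | Path) -> Corpus:
    """Load a corpus from a JSON manifest.

    The manifest lists melody files relative to its own directory::

        {"melodies": [{"file": "m1.csv", "style": "simple"}, ...]}

    ``.csv`` entries are note tables; ``.mid``/``.midi`` entries are SMF files.
    """
    path = Path(path)
    manifest = json.loads(path.read_text(encoding="utf-8"))
    melodies = []
    for entry in manifest.get("melodies", []):
        fpath = path.parent / entry["file"]
        style = entry.get("style", "synthetic")
        if fpath.suffix.lower() in (".mid", ".midi"):
            melody = read_midi_melody(fpath)
            melody = replace(melody, style=style)
        else:
            melody = read_note_table(fpath, style=style)
        melodies.append(melody)
    return Corpus(melodies=melodies)


def write_corpus_manifest(corpus: Corpus, directory: str | Path,
                          name: str = "manifest.json") -> Path:
    """Write every melody as a note table plus a manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for m in corpus.melodies:
        fname = f"{m.id}.csv"
        write_note_table(m, directory / fname)
        entries.append({"file": fname, "style": m.style})
    manifest_path = directory / name
    manifest_path.write_text(
        json.dumps({"melodies": entries}, indent=1), encoding="utf-8"
    )
    return manifest_path
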