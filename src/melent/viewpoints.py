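"""Linked viewpoint representation of melodic events.

The expectation model does not predict raw pitch directly; each note is
re-described as a linked symbol combining *pitch interval* (signed semitone
step from the previous note), *scale degree* (chromatic distance above the
tonic, modulo 12) and, for rhythmic styles, the *inter-onset-interval contour*
(sign of the change between consecutive IOIs).  The mapping from candidate
pitch to symbol is injective for a fixed context, so a distribution over
symbols converts back to a distribution over candidate pitches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .melody_io import Melody

__all__ = ["Key", "ViewpointSymbol", "derive_viewpoints", "symbol_for_candidate"]

MAJOR, MINOR = "major", "minor"


@dataclass(frozen=True)
class Key:
    """A tonal centre: tonic pitch class (0-11, C = 0) and mode."""

    tonic: int
    mode: str = MAJOR

    def __post_init__(self) -> None:
        if not 0 <= self.tonic <= 11:
            raise ValueError(f"tonic must be a pitch class 0-11, got {self.tonic}")
        if self.mode not in (MAJOR, MINOR):
            raise ValueError(f"mode must be 'major' or 'minor', got {self.mode!r}")


@dataclass(frozen=True)
class ViewpointSymbol:
    """Linked (pitch-interval, scale-degree[, IOI-contour]) description of a note.

    ``pitch_interval`` is None for the first note of a melody; ``ioi_contour``
    is None for the first two notes or when the style carries no rhythm.
    """

    pitch_interval: Optional[int]
    scale_degree: int
    ioi_contour: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.scale_degree <= 11:
            raise ValueError(f"scale_degree must be in 0-11, got {self.scale_degree}")
        if self.ioi_contour not in (None, -1, 0, 1):
            raise ValueError(f"ioi_contour must be -1/0/+1, got {self.ioi_contour}")


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def derive_viewpoints(melody: Melody, key: Key,
                      include_ioi_contour: bool = False) -> list[ViewpointSymbol]:
    """Derive the linked symbol sequence for a melody under a key.

    Element ``i`` carries ``pitch_interval = pitch_i - pitch_{i-1}`` (absent at
    i=0), ``scale_degree = (pitch_i - tonic) mod 12``, and — when requested —
    ``ioi_contour = sign(IOI_i - IOI_{i-1})`` with ``IOI_i = onset_i -
    onset_{i-1}`` (absent at i<2).
    """
    pitches = melody.pitches
    onsets = [e.onset for e in melody.events]
    symbols = []
    for i, p in enumerate(pitches):
        interval = None if i == 0 else p - pitches[i - 1]
        contour = None
        if include_ioi_contour and i >= 2:
            ioi_cur = onsets[i] - onsets[i - 1]
            ioi_prev = onsets[i - 1] - onsets[i - 2]
            contour = _sign(ioi_cur - ioi_prev)
        symbols.append(
            ViewpointSymbol(
                pitch_interval=interval,
                scale_degree=(p - key.tonic) % 12,
                ioi_contour=contour,
            )
        )
    return symbols


def symbol_for_candidate(prev_pitch: Optional[int], candidate_pitch: int,
                         key: Key,
                         ioi_contour: Optional[int] = None) -> ViewpointSymbol:
    """Symbol a candidate next-pitch would produce after ``prev_pitch``.

    With ``prev_pitch=None`` (predicting the first event) the symbol carries
    the scale degree only.  For fixed ``prev_pitch``/``key``/``ioi_contour``
    the mapping is injective in ``candidate_pitch`` over any within-octave-span
    alphabet, since the pitch interval alone determines the candidate.
    """
    interval = None if prev_pitch is None else candidate_pitch - prev_pitch
    return ViewpointSymbol(
        pitch_interval=interval,
        scale_degree=(candidate_pitch - key.tonic) % 12,
        ioi_contour=ioi_contour,
    )
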