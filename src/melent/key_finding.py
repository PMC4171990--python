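"""Krumhansl-Schmuckler style key estimation by profile correlation.

A melody's duration-weighted pitch-class distribution is correlated against a
key profile rotated to each of the 24 candidate keys (12 tonics x 2 modes);
the best-correlating key wins.  Two profile sets ship in ``data/profiles.json``:
the Krumhansl-Kessler probe-tone profiles and Temperley's modified values
(the default here, matching the variant used for perceptual key induction).
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

from .melody_io import Melody
from .viewpoints import Key, MAJOR, MINOR

__all__ = ["estimate_key", "load_profiles", "pitch_class_distribution"]

PROFILE_SETS = ("krumhansl_kessler", "temperley")


@lru_cache(maxsize=None)
def load_profiles() -> dict:
    """Key-profile table from the packaged data file."""
    text = resources.files("melent.data").joinpath("profiles.json").read_text()
    return json.loads(text)


def pitch_class_distribution(melody: Melody,
                             weighting: str = "duration") -> np.ndarray:
    """12-vector of pitch-class weight totals (duration- or count-weighted)."""
    if weighting not in ("duration", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    dist = np.zeros(12)
    for e in melody.events:
        dist[e.pitch % 12] += e.duration if weighting == "duration" else 1.0
    return dist


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt((da ** 2).sum() * (db ** 2).sum())
    if denom == 0.0:
        return 0.0  # flat input: every key correlates equally (tie-break decides)
    return float((da * db).sum() / denom)


def estimate_key(melody: Melody, profile_set: str = "temperley",
                 weighting: str = "duration") -> Key:
    """Estimate the induced key of a melodic segment.

    Returns the key maximizing the Pearson correlation between the melody's
    weighted pitch-class distribution and the profile rotated to that key.
    Ties break deterministically: lowest tonic first, major before minor.
    """
    if profile_set not in PROFILE_SETS:
        raise ValueError(f"unknown profile set {profile_set!r}")
    profiles = load_profiles()[profile_set]
    dist = pitch_class_distribution(melody, weighting=weighting)
    best: tuple[float, int, int] | None = None
    best_key: Key | None = None
    for mode_idx, mode in enumerate((MAJOR, MINOR)):
        profile = np.asarray(profiles[mode], dtype=float)
        for tonic in range(12):
            rotated = np.roll(profile, tonic)
            r = _correlation(dist, rotated)
            rank = (-r, tonic, mode_idx)  # lexicographic tie-break
            if best is None or rank < best:
                best = rank
                best_key = Key(tonic=tonic, mode=mode)
    assert best_key is not None
    return best_key
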