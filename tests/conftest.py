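"""Shared fixtures: toy melodies, synthetic corpora, and one full run."""

from __future__ import annotations

import numpy as np
import pytest

from melent.melody_io import Corpus, Melody, NoteEvent
from melent.viewpoints import Key


def melody_from_pitches(pitches, onsets=None, durations=None, style="simple",
                        mid="toy", key=None, phrase_starts=None):
    """Build a melody from parallel value lists with sensible defaults."""
    n = len(pitches)
    onsets = list(onsets) if onsets is not None else list(range(n))
    durations = list(durations) if durations is not None else [1.0] * n
    flags = (list(phrase_starts) if phrase_starts is not None
             else [i == 0 for i in range(n)])
    events = tuple(
        NoteEvent(pitch=p, onset=float(o), duration=float(d), phrase_start=f)
        for p, o, d, f in zip(pitches, onsets, durations, flags)
    )
    return Melody(id=mid, events=events, style=style, key=key)


@pytest.fixture
def c_major():
    return Key(tonic=0, mode="major")


@pytest.fixture
def toy_melody():
    """Ten-note C-major noodle on five distinct pitches, two phrases."""
    return melody_from_pitches(
        [60, 62, 64, 65, 67, 65, 64, 62, 60, 64],
        phrase_starts=[True, False, False, False, False,
                       True, False, False, False, False],
        key=Key(0, "major"))


@pytest.fixture
def toy_corpus(toy_melody):
    second = melody_from_pitches(
        [64, 65, 67, 65, 64, 62, 60, 62, 64, 60], mid="toy2",
        key=Key(0, "major"))
    return Corpus(melodies=[toy_melody, second])


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-configuration pipeline run (seed 1), shared."""
    from melent.pipeline import run_experiment_pipeline

    out = tmp_path_factory.mktemp("pipeline_run")
    return run_experiment_pipeline({"seed": 1}, out)
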