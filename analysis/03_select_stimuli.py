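#!/usr/bin/env python
"""Two-stage entropy-driven stimulus selection.

Scores every note of both stimulus corpora with the trained model, takes the
18 highest- and lowest-entropy eligible notes per corpus, wraps them in
phrase-respecting contexts, assigns nine chromatic probe tones each, and
keeps the 6 most extreme candidates per style x entropy cell by 9-tone
entropy (24 stimuli total).  Writes stimuli.json and the per-note score
table.

Usage: python analysis/03_select_stimuli.py  (after 02_train_models.py)
"""

import json
from pathlib import Path

import pandas as pd

from melent.expectation_model import ModelConfig, NGramStore
from melent.melody_io import read_corpus_manifest
from melent.stimulus_selection import (
    MIN_CONTEXT_NOTES,
    Rejection,
    StimulusSet,
    extract_candidate_context,
    score_corpus_notes,
    select_candidate_notes,
    select_stimulus_set,
)

OUT = Path("results/analysis")
K_PER_EXTREME = 18
PER_CELL = 6


def main() -> None:
    alphabet = tuple(json.loads((OUT / "alphabet.json").read_text()))
    all_scores = []
    all_stimuli = []
    for style in ("simple", "complex"):
        corpus = read_corpus_manifest(OUT / f"corpus_{style}"
                                      / "manifest.json")
        ltm = NGramStore.load(OUT / f"ltm_{style}.json")
        config = ModelConfig(include_ioi_contour=(style == "complex"),
                             alphabet_policy="chromatic_span")
        scores = score_corpus_notes(corpus, ltm, config, alphabet=alphabet)
        scores["style"] = style
        all_scores.append(scores)
        eligible = scores[scores["note_index"] >= MIN_CONTEXT_NOTES]
        table = select_candidate_notes(eligible, K_PER_EXTREME)
        candidates, rejected = [], 0
        for row in table.itertuples(index=False):
            res = extract_candidate_context(corpus, row.melody_id,
                                            row.note_index, row.entropy_class,
                                            entropy_37=row.entropy)
            if isinstance(res, Rejection):
                rejected += 1
            else:
                candidates.append(res)
        print(f"{style}: scored {len(scores)} notes; "
              f"{len(candidates)} candidate contexts ({rejected} rejected)")
        subset = select_stimulus_set(candidates, ltm, config,
                                     per_cell=PER_CELL, alphabet=alphabet)
        all_stimuli.extend(subset.stimuli)

    pd.concat(all_scores).to_csv(OUT / "note_entropies.csv", index=False)
    stimuli = StimulusSet(stimuli=all_stimuli, config_label="BOTH-ordervar")
    stimuli.save(OUT / "stimuli.json")

    frame = pd.DataFrame(
        [{"context": s.label, "style": s.style, "cell": s.entropy_class,
          "entropy_37": s.entropy_37, "entropy_9": s.entropy_9}
         for s in stimuli.stimuli])
    print(frame.groupby(["style", "cell"])[["entropy_37", "entropy_9"]]
          .mean().round(3))
    print(f"selected {len(stimuli)} stimuli "
          f"({sum(len(s.probe_pitches) for s in stimuli.stimuli)} "
          f"probe trials)")


if __name__ == "__main__":
    main()
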