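#!/usr/bin/env python
"""Train the long-term sub-models on the synthetic training corpus.

One store per stimulus style: the complex style's viewpoint system adds the
IOI-contour component, so its statistics differ from the simple style's even
though both train on the same corpus.  Models are persisted as JSON.

Usage: python analysis/02_train_models.py  (after 01_generate_corpora.py)
"""

import json
from pathlib import Path

from melent.expectation_model import ModelConfig, build_alphabet, train_ltm
from melent.melody_io import read_corpus_manifest

OUT = Path("results/analysis")


def main() -> None:
    training = read_corpus_manifest(OUT / "corpus_training" / "manifest.json")
    alphabet = build_alphabet(training, policy="chromatic_span")
    (OUT / "alphabet.json").write_text(json.dumps(list(alphabet)))
    print(f"prediction alphabet: {len(alphabet)} chromatic pitches "
          f"({alphabet[0]}-{alphabet[-1]})")

    for style, include_ioi in (("simple", False), ("complex", True)):
        config = ModelConfig(configuration="LTM",
                             include_ioi_contour=include_ioi,
                             alphabet_policy="chromatic_span")
        ltm = train_ltm(training, config)
        ltm.save(OUT / f"ltm_{style}.json")
        print(f"{style} LTM: {len(ltm.counts)} contexts, "
              f"{ltm.total_events()} order-0 events "
              f"(IOI contour: {include_ioi})")


if __name__ == "__main__":
    main()
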