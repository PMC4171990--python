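#!/usr/bin/env python
"""Generate the synthetic training and stimulus corpora.

Builds one training corpus spanning a 37-pitch chromatic range (B2-B5) and
two stimulus corpora — an isochronous "simple" style (C4-F5) and a rhythmic
"complex" style (A3-A5) — from graded-entropy Markov grammars, and writes
them as note-table corpora with JSON manifests under results/analysis/.

Usage: python analysis/01_generate_corpora.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from melent.melody_io import write_corpus_manifest
from melent.pipeline import _stage_seeds, build_corpora, load_config
from melent.synthetic_data import analytic_chain_entropy

OUT = Path("results/analysis")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    config = load_config({"seed": args.seed})
    rng_train, rng_simple, rng_complex, *_ = _stage_seeds(args.seed)
    training, stimulus = build_corpora(config, rng_train, rng_simple,
                                       rng_complex)

    OUT.mkdir(parents=True, exist_ok=True)
    write_corpus_manifest(training, OUT / "corpus_training")
    for style, corpus in stimulus.items():
        write_corpus_manifest(corpus, OUT / f"corpus_{style}")

    summary = {
        "seed": args.seed,
        "training": {"melodies": len(training), "events": training.n_events,
                     "pitch_range": training.pitch_range},
        **{style: {"melodies": len(c), "events": c.n_events,
                   "pitch_range": c.pitch_range}
           for style, c in stimulus.items()},
    }
    (OUT / "01_corpora.json").write_text(json.dumps(summary, indent=1))
    print(f"training corpus: {len(training)} melodies, "
          f"{training.n_events} events, pitches "
          f"{training.pitch_range[0]}-{training.pitch_range[1]}")
    for style, corpus in stimulus.items():
        print(f"{style} corpus: {len(corpus)} melodies, "
              f"{corpus.n_events} events, pitches "
              f"{corpus.pitch_range[0]}-{corpus.pitch_range[1]}")


if __name__ == "__main__":
    main()
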