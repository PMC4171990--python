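#!/usr/bin/env python
"""Simulate musician and non-musician listeners on the selected stimuli.

Computes the standard model's per-probe information content and per-context
entropy, then generates 9-point unexpectedness and explicit-uncertainty
ratings for 17 listeners per group (musicians: rating noise SD 1.0;
non-musicians: 2.0; 2% lapse rate).  Writes tidy ratings CSVs.

Usage: python analysis/04_simulate_listeners.py --seed 1  (after 03)
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from melent.expectation_model import ModelConfig, NGramStore
from melent.info_measures import entropy, information_content
from melent.stimulus_selection import StimulusSet, target_distribution
from melent.synthetic_data import (
    default_listener_specs,
    simulate_listener_ratings,
)

OUT = Path("results/analysis")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-per-group", type=int, default=17)
    args = parser.parse_args()

    stimuli = StimulusSet.load(OUT / "stimuli.json")
    alphabet = tuple(json.loads((OUT / "alphabet.json").read_text()))
    ltms = {style: NGramStore.load(OUT / f"ltm_{style}.json")
            for style in ("simple", "complex")}

    ic_rows, ent = [], {}
    for stim in stimuli.stimuli:
        config = ModelConfig(include_ioi_contour=(stim.style == "complex"),
                             alphabet_policy="chromatic_span")
        d = target_distribution(stim, ltms[stim.style], stim.key_used[0],
                                config, alphabet)
        ent[stim.label] = entropy(d)
        for probe in stim.probe_pitches:
            ic_rows.append((stim.label, probe, information_content(d, probe)))
    model_ic = pd.DataFrame(ic_rows, columns=["context", "probe", "ic"])
    model_entropy = pd.Series(ent)
    model_ic.to_csv(OUT / "model_ic.csv", index=False)
    model_entropy.rename("entropy").to_csv(OUT / "model_entropy.csv",
                                           index_label="context")

    rng = np.random.default_rng(
        np.random.SeedSequence(args.seed).spawn(8)[3])
    ratings = simulate_listener_ratings(
        stimuli, model_ic, model_entropy, default_listener_specs(),
        n_per_group=args.n_per_group, seed=rng)
    ratings.save(OUT / "ratings")
    print(f"simulated {ratings.profiles.shape[0]} listeners: "
          f"{len(ratings.unexpectedness)} probe-trial ratings, "
          f"{len(ratings.explicit)} explicit-uncertainty ratings")
    print(ratings.profiles.groupby("group")["gmsi_training"]
          .agg(["mean", "std"]).round(2))


if __name__ == "__main__":
    main()
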