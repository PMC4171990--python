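#!/usr/bin/env python
"""Model-comparison grid: which configuration fits the listeners best?

Evaluates every order bound (0-4, variable) x configuration (STM, LTM,
BOTH), plus the Schmuckler difference scores and the three-predictor
Implication-Realization regression, against the simulated listeners'
unexpectedness, inferred uncertainty, and explicit uncertainty.

Usage: python analysis/06_model_comparison.py  (after 04)
"""

import json
from pathlib import Path

import pandas as pd

from melent.behavioral_analysis import (
    RatingDataset,
    default_config_grid,
    model_comparison_grid,
)
from melent.expectation_model import NGramStore
from melent.stimulus_selection import StimulusSet

OUT = Path("results/analysis")


def main() -> None:
    stimuli = StimulusSet.load(OUT / "stimuli.json")
    ratings = RatingDataset.load(OUT / "ratings")
    alphabet = tuple(json.loads((OUT / "alphabet.json").read_text()))
    ltms = {style: NGramStore.load(OUT / f"ltm_{style}.json")
            for style in ("simple", "complex")}

    table, traces = model_comparison_grid(
        stimuli, ratings, ltms, default_config_grid(include_ioi_contour=True),
        alphabet)
    table.to_csv(OUT / "comparison_grid.csv")
    for label, trace in traces.items():
        trace.to_csv(OUT / f"trace_{label}.csv", index=False)

    pd.set_option("display.width", 160)
    cols = ["ic_vs_unexpectedness_all", "entropy_vs_inferred_all",
            "entropy_vs_explicit_all"]
    print(table[cols].round(3))
    best = table["ic_vs_unexpectedness_all"].idxmax()
    print(f"\nbest IC-vs-unexpectedness fit: {best} "
          f"(rho = {table.loc[best, 'ic_vs_unexpectedness_all']:.3f}); "
          f"IR regression R = "
          f"{table.loc['ir_regression', 'ic_vs_unexpectedness_all']:.3f}")


if __name__ == "__main__":
    main()
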