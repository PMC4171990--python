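#!/usr/bin/env python
"""Behavioral analysis of the simulated rating data.

Runs the full statistics battery: inferred uncertainty (both orientations),
Tukey-fence outlier exclusion, 2x2x2 mixed ANOVAs per dependent variable,
the rank-transform ANOVA, Cronbach's alpha, per-participant model fits with
group comparisons, and the Williams test on group-averaged correlations.
Also reports the demographics checks on the simulated participant profiles.

Usage: python analysis/05_behavioral_analysis.py  (after 04)
"""

import json
from pathlib import Path

import pandas as pd

from melent.behavioral_analysis import (
    MUSICIAN,
    NONMUSICIAN,
    RatingDataset,
    chi_square_2x2,
    pooled_t,
    welch_t,
)
from melent.pipeline import analyze_ratings
from melent.stimulus_selection import StimulusSet

OUT = Path("results/analysis")


def main() -> None:
    stimuli = StimulusSet.load(OUT / "stimuli.json")
    ratings = RatingDataset.load(OUT / "ratings")
    model_ic = pd.read_csv(OUT / "model_ic.csv")
    model_entropy = pd.read_csv(OUT / "model_entropy.csv",
                                index_col="context")["entropy"]

    results = analyze_ratings(stimuli, ratings, model_ic, model_entropy)

    for name, table in results["anova"].items():
        table.to_csv(OUT / f"anova_{name}.csv")
        print(f"\nANOVA ({name}):")
        print(table[["F", "df1", "df2", "p"]].round(4))
    results["model_fits"].to_csv(OUT / "model_fits.csv", index=False)

    print("\nCronbach's alpha (participants as items):",
          {k: round(v, 3) for k, v in results["alpha"].items()})
    print("group model-fit comparison:",
          json.dumps(results["group_fit_comparison"], indent=1,
                     default=float))
    print("Williams test on group-averaged unexpectedness correlations:",
          {k: round(v, 3) if isinstance(v, float) else v
           for k, v in results["williams"].items()})

    # demographics checks on the simulated profiles
    prof = ratings.profiles
    mus = prof[prof["group"] == MUSICIAN]
    non = prof[prof["group"] == NONMUSICIAN]
    t_tr, df_tr = welch_t(non["gmsi_training"].mean(),
                          non["gmsi_training"].std(ddof=1), len(non),
                          mus["gmsi_training"].mean(),
                          mus["gmsi_training"].std(ddof=1), len(mus))
    t_age, df_age = pooled_t(mus["age"].mean(), mus["age"].std(ddof=1),
                             len(mus), non["age"].mean(),
                             non["age"].std(ddof=1), len(non))
    females = prof.groupby("group")["gender"].apply(
        lambda g: (g == "female").sum())
    males = prof.groupby("group")["gender"].apply(
        lambda g: (g == "male").sum())
    chi2 = chi_square_2x2([[females[MUSICIAN], males[MUSICIAN]],
                           [females[NONMUSICIAN], males[NONMUSICIAN]]])
    print(f"\nsimulated demographics: training Welch t({df_tr:.1f}) = "
          f"{t_tr:.2f}; age t({df_age}) = {t_age:.2f}; "
          f"gender chi2(1) = {chi2:.2f}")


if __name__ == "__main__":
    main()
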