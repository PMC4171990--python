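"""End-to-end experiment pipeline: train, select stimuli, simulate, analyze.

One seeded run mirrors the study design: a long-term model is trained on a
synthetic corpus; per-note entropies over two stimulus corpora (simple /
complex style) drive the two-stage stimulus selection (18 highest- and
lowest-entropy notes per corpus -> candidate contexts -> 6 stimuli per
style x entropy cell); simulated musician and non-musician listeners rate
probe-tone unexpectedness and explicit uncertainty; and the behavioral
analysis plus the model-comparison grid are computed and written out as
CSV/JSON tables together with a run manifest.

A single top-level seed is expanded into independent per-stage streams, so
re-running a config is bit-identical stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavioral_analysis import (
    MUSICIAN,
    NONMUSICIAN,
    RatingDataset,
    condition_means,
    cronbach_alpha,
    exclude_outliers,
    fisher_z,
    inferred_uncertainty_table,
    mixed_anova,
    model_comparison_grid,
    participant_model_fit,
    pooled_t,
    rank_transform_anova,
    welch_t,
    williams_t,
)
from .expectation_model import (
    BOTH,
    ModelConfig,
    NGramStore,
    VARIABLE,
    build_alphabet,
    train_ltm,
)
from .info_measures import entropy, information_content
from .melody_io import Corpus
from .stimulus_selection import (
    Rejection,
    StimulusSet,
    extract_candidate_context,
    score_corpus_notes,
    select_candidate_notes,
    select_stimulus_set,
    target_distribution,
)
from .synthetic_data import (
    GrammarSpec,
    default_listener_specs,
    generate_markov_corpus,
    graded_entropy_grammar,
    simulate_listener_ratings,
)

log = logging.getLogger("melent.pipeline")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_experiment_pipeline",
           "PipelineConfigError"]


class PipelineConfigError(ValueError):
    """The run configuration violates the documented schema."""


#: Default run configuration.  Corpus sizes are scaled-down analogues of the
#: study corpora chosen to keep a full desk run in minutes; the design
#: numbers (18 extremes per corpus, 6 stimuli per cell, 9 probes, 17
#: listeners per group) mirror the study.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "training": {
        "pitch_range": [47, 83],  # B2-B5: a 37-pitch chromatic span
        "n_melodies": 60,
        "notes_per_melody": 40,
        "style": "rhythmic",
    },
    "stimulus_corpora": {
        "simple": {"pitch_range": [60, 77], "style": "isochronous",
                   "n_melodies": 40, "notes_per_melody": 40},
        "complex": {"pitch_range": [57, 81], "style": "rhythmic",
                    "n_melodies": 40, "notes_per_melody": 40},
    },
    "selection": {"k_per_extreme": 18, "per_cell": 6},
    "model": {"order_bound": "variable", "configuration": BOTH,
              "include_ioi_contour": True, "combination_bias": 1.0,
              "escape_method": "C", "update_exclusion": True},
    "listeners": {"n_per_group": 17, "noise_musician": 1.0,
                  "noise_nonmusician": 2.0, "lapse_rate": 0.02,
                  "familiar_rate": 0.0},
    "comparison": {"run_grid": True},
}

_SCHEMA_KEYS = set(DEFAULT_CONFIG)


def load_config(path_or_dict) -> dict:
    """Load and validate a run config (YAML path or dict), merging defaults."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text(encoding="utf-8"))
    else:
        raw = dict(path_or_dict or {})
    if not isinstance(raw, dict):
        raise PipelineConfigError("config root must be a mapping")
    unknown = set(raw) - _SCHEMA_KEYS
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in raw.items():
        if key == "stimulus_corpora" and isinstance(value, dict):
            for style, overrides in value.items():
                if style not in config[key]:
                    raise PipelineConfigError(
                        f"unknown stimulus corpus {style!r}")
                bad = set(overrides) - set(config[key][style])
                if bad:
                    raise PipelineConfigError(
                        f"unknown keys under stimulus_corpora.{style}: "
                        f"{sorted(bad)}")
                config[key][style].update(overrides)
        elif isinstance(value, dict):
            sub_unknown = set(value) - set(config[key])
            if sub_unknown:
                raise PipelineConfigError(
                    f"unknown keys under {key!r}: {sorted(sub_unknown)}")
            config[key].update(value)
        else:
            config[key] = value
    return config


def _model_config(model_cfg: dict, include_ioi: Optional[bool] = None
                  ) -> ModelConfig:
    order = model_cfg["order_bound"]
    if order in ("variable", None):
        order = VARIABLE
    return ModelConfig(
        order_bound=order,
        configuration=model_cfg["configuration"],
        escape_method=model_cfg.get("escape_method", "C"),
        update_exclusion=model_cfg.get("update_exclusion", True),
        combination_bias=model_cfg.get("combination_bias", 1.0),
        include_ioi_contour=(model_cfg["include_ioi_contour"]
                             if include_ioi is None else include_ioi),
        alphabet_policy="chromatic_span",
    )


def _stage_seeds(seed: int, n: int = 8) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def build_corpora(config: dict, rng_train, rng_simple, rng_complex
                  ) -> tuple[Corpus, dict[str, Corpus]]:
    """Training corpus plus the two stimulus corpora from graded grammars."""
    tr = config["training"]
    train_grammar = graded_entropy_grammar(
        tuple(tr["pitch_range"]), style=tr["style"], seed=rng_train)
    training = generate_markov_corpus(
        train_grammar, tr["n_melodies"], tr["notes_per_melody"],
        seed=rng_train, id_prefix="train")
    stimulus = {}
    for style, rng in (("simple", rng_simple), ("complex", rng_complex)):
        sc = config["stimulus_corpora"][style]
        grammar = graded_entropy_grammar(
            tuple(sc["pitch_range"]), style=sc["style"], seed=rng)
        stimulus[style] = generate_markov_corpus(
            grammar, sc["n_melodies"], sc["notes_per_melody"], seed=rng,
            id_prefix=style[:4])
    return training, stimulus


def select_stimuli(training: Corpus, stimulus_corpora: dict[str, Corpus],
                   config: dict) -> tuple[StimulusSet, dict, tuple[int, ...]]:
    """Stages 1-4 of the selection procedure; returns stimuli + LTM stores.

    The two styles use different viewpoint systems (the complex style adds
    the IOI-contour component), so the shared training corpus yields one
    trained store per style.
    """
    sel = config["selection"]
    alphabet = build_alphabet(training, policy="chromatic_span")
    ltms: dict[str, NGramStore] = {}
    all_stimuli = []
    for style, corpus in stimulus_corpora.items():
        mc = _model_config(config["model"],
                           include_ioi=(style == "complex"
                                        and config["model"]
                                        ["include_ioi_contour"]))
        ltm = train_ltm(training, mc)
        ltms[style] = ltm
        scores = score_corpus_notes(corpus, ltm, mc, alphabet=alphabet)
        # only notes deep enough to ever carry a qualifying context are
        # eligible as targets (early notes have flat, short-context
        # predictions and could never be segmented anyway)
        from .stimulus_selection import MIN_CONTEXT_NOTES

        eligible = scores[scores["note_index"] >= MIN_CONTEXT_NOTES]
        candidates_tbl = select_candidate_notes(eligible, sel["k_per_extreme"])
        candidates = []
        n_rejected = 0
        for row in candidates_tbl.itertuples(index=False):
            result = extract_candidate_context(
                corpus, row.melody_id, row.note_index, row.entropy_class,
                entropy_37=row.entropy)
            if isinstance(result, Rejection):
                n_rejected += 1
            else:
                candidates.append(result)
        log.info("style %s: %d candidates (%d rejected)", style,
                 len(candidates), n_rejected)
        subset = select_stimulus_set(candidates, ltm, mc,
                                     per_cell=sel["per_cell"],
                                     alphabet=alphabet)
        all_stimuli.extend(subset.stimuli)
    stimuli = StimulusSet(stimuli=all_stimuli,
                          config_label=_model_config(config["model"]).label())
    return stimuli, ltms, alphabet


def model_outputs(stimuli: StimulusSet, ltms: dict, alphabet,
                  config: dict) -> tuple[pd.DataFrame, pd.Series]:
    """Standard-configuration IC per probe trial and entropy per context."""
    ic_rows = []
    ent = {}
    for stim in stimuli.stimuli:
        mc = _model_config(config["model"],
                           include_ioi=(stim.style == "complex"
                                        and config["model"]
                                        ["include_ioi_contour"]))
        d = target_distribution(stim, ltms[stim.style], stim.key_used[0], mc,
                                alphabet)
        ent[stim.label] = entropy(d)
        for probe in stim.probe_pitches:
            ic_rows.append((stim.label, probe, information_content(d, probe)))
    ic = pd.DataFrame(ic_rows, columns=["context", "probe", "ic"])
    return ic, pd.Series(ent)


def analyze_ratings(stimuli: StimulusSet, ratings: RatingDataset,
                    model_ic: pd.DataFrame, model_entropy: pd.Series
                    ) -> dict:
    """The behavioral analysis battery on one rating dataset.

    Returns a dict of tables/scalars: per-DV ANOVA tables after Tukey-fence
    outlier exclusion, the rank-transform ANOVA of inferred uncertainty,
    Cronbach's alpha per DV, per-participant model fits with group
    comparisons, and the Williams test on group-averaged correlations.
    """
    clean = ratings.without_familiar()
    groups = clean.group_of()
    order = [s.label for s in stimuli.stimuli]

    inferred = inferred_uncertainty_table(clean)
    # the expectedness-entropy variant: the two orientations can disagree
    # (the raw-unexpectedness entropy is heavily compressed near 1), so
    # both are analyzed and reported
    inferred_rev = inferred_uncertainty_table(clean, orientation="reversed")
    explicit = clean.explicit.rename(columns={"rating": "value"})
    unexp_ctx = (clean.unexpectedness
                 .groupby(["participant", "context"], sort=True)["rating"]
                 .mean().reset_index().rename(columns={"rating": "value"}))

    results: dict = {"anova": {}, "alpha": {}, "outliers": {}}
    for name, values in (("explicit", explicit), ("inferred", inferred),
                         ("inferred_reversed", inferred_rev),
                         ("unexpectedness", unexp_ctx)):
        cells = condition_means(values, stimuli, groups)
        wide = cells.pivot_table(index="participant",
                                 columns=["complexity", "entropy"],
                                 values="value")
        retained, report = exclude_outliers(wide)
        results["outliers"][name] = report
        kept = cells[cells["participant"].isin(retained)]
        results["anova"][name] = mixed_anova(kept)
        if name == "inferred":
            results["anova"]["inferred_rank"] = rank_transform_anova(cells)
        item_matrix = values.pivot_table(index="context",
                                         columns="participant",
                                         values="value").reindex(order)
        results["alpha"][name] = cronbach_alpha(item_matrix.dropna())

    # per-participant model fits
    probe_order = [(s.label, p) for s in stimuli.stimuli
                   for p in s.probe_pitches]
    ic_series = model_ic.set_index(["context", "probe"])["ic"].reindex(
        probe_order)
    fit_rows = []
    for pid, grp in groups.items():
        expl_p = explicit[explicit["participant"] == pid].set_index(
            "context")["value"].reindex(order)
        inf_p = inferred[inferred["participant"] == pid].set_index(
            "context")["value"].reindex(order)
        un_p = (clean.unexpectedness[clean.unexpectedness["participant"]
                                     == pid]
                .set_index(["context", "probe"])["rating"]
                .reindex(probe_order))
        row = {"participant": pid, "group": grp}
        for label, series, model in (
                ("explicit_fit", expl_p, model_entropy.reindex(order)),
                ("inferred_fit", inf_p, model_entropy.reindex(order)),
                ("unexpectedness_fit", un_p, ic_series)):
            pair = pd.concat([series, model], axis=1).dropna()
            fit = participant_model_fit(pair.iloc[:, 0], pair.iloc[:, 1])
            row[label] = fit.r
            row[f"{label}_z"] = fit.z
        fit_rows.append(row)
    fits = pd.DataFrame(fit_rows)
    results["model_fits"] = fits

    comparisons = {}
    for label in ("explicit_fit", "inferred_fit", "unexpectedness_fit"):
        mus = fits.loc[fits["group"] == MUSICIAN, f"{label}_z"]
        non = fits.loc[fits["group"] == NONMUSICIAN, f"{label}_z"]
        t, df = welch_t(non.mean(), non.std(ddof=1), len(non),
                        mus.mean(), mus.std(ddof=1), len(mus))
        comparisons[label] = {
            "mean_musician": float(mus.mean()),
            "mean_non_musician": float(non.mean()),
            "welch_t": t, "welch_df": df,
        }
    results["group_fit_comparison"] = comparisons

    # Williams test: do group-averaged unexpectedness ratings fit the model
    # differently for musicians vs non-musicians?
    def group_mean_unexp(who):
        sub = clean.unexpectedness.merge(groups.rename("group"),
                                         left_on="participant",
                                         right_index=True)
        if who is not None:
            sub = sub[sub["group"] == who]
        return sub.groupby(["context", "probe"], sort=True)["rating"].mean(
            ).reindex(probe_order)

    mus_mean = group_mean_unexp(MUSICIAN)
    non_mean = group_mean_unexp(NONMUSICIAN)
    aligned = pd.concat([ic_series, mus_mean, non_mean], axis=1).dropna()
    r12 = aligned.iloc[:, 0].corr(aligned.iloc[:, 1])
    r13 = aligned.iloc[:, 0].corr(aligned.iloc[:, 2])
    r23 = aligned.iloc[:, 1].corr(aligned.iloc[:, 2])
    t_w, df_w = williams_t(r12, r13, r23, len(aligned))
    results["williams"] = {"r_model_musician": float(r12),
                           "r_model_non_musician": float(r13),
                           "r_between_groups": float(r23),
                           "t": t_w, "df": df_w}
    return results


def run_experiment_pipeline(config, out_dir: str | Path) -> dict:
    """Execute every stage under one seed and write the result tables.

    Writes stimuli.json, the four ratings CSVs, ANOVA/fit/comparison tables
    and manifest.json into ``out_dir``; returns the in-memory results.
    """
    config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    (rng_train, rng_simple, rng_complex, rng_listeners, *_ ) = _stage_seeds(seed)

    log.info("stage 1: corpora (seed %d)", seed)
    training, stimulus_corpora = build_corpora(config, rng_train, rng_simple,
                                               rng_complex)
    log.info("stage 2-3: training + stimulus selection")
    stimuli, ltms, alphabet = select_stimuli(training, stimulus_corpora,
                                             config)
    log.info("stage 4: model outputs for %d stimuli", len(stimuli))
    model_ic, model_entropy = model_outputs(stimuli, ltms, alphabet, config)

    log.info("stage 5: simulating listeners")
    li = config["listeners"]
    listeners = default_listener_specs(li["noise_musician"],
                                       li["noise_nonmusician"],
                                       li["lapse_rate"])
    ratings = simulate_listener_ratings(
        stimuli, model_ic, model_entropy, listeners,
        n_per_group=li["n_per_group"], seed=rng_listeners,
        familiar_rate=li["familiar_rate"])

    log.info("stage 6: behavioral analysis")
    results = analyze_ratings(stimuli, ratings, model_ic, model_entropy)

    grid_table = None
    if config["comparison"]["run_grid"]:
        log.info("stage 7: model-comparison grid")
        from .behavioral_analysis import default_config_grid

        grid_table, _ = model_comparison_grid(
            stimuli, ratings, ltms,
            default_config_grid(config["model"]["include_ioi_contour"]),
            alphabet)
        grid_table.to_csv(out_dir / "comparison_grid.csv")

    # ---- outputs ----
    stimuli.save(out_dir / "stimuli.json")
    ratings.save(out_dir / "ratings")
    for name, table in results["anova"].items():
        table.to_csv(out_dir / f"anova_{name}.csv")
    results["model_fits"].to_csv(out_dir / "model_fits.csv", index=False)
    summary = {
        "seed": seed,
        "n_stimuli": len(stimuli),
        "n_trials": int(len(stimuli) * 9),
        "alphabet_size": len(alphabet),
        "alpha": results["alpha"],
        "group_fit_comparison": results["group_fit_comparison"],
        "williams": results["williams"],
        "anova_p": {name: {effect: float(tbl.loc[effect, "p"])
                           for effect in tbl.index}
                    for name, tbl in results["anova"].items()},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1),
                                          encoding="utf-8")
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                           encoding="utf-8")
    results.update({"stimuli": stimuli, "ratings": ratings,
                    "model_ic": model_ic, "model_entropy": model_entropy,
                    "alphabet": alphabet, "ltms": ltms, "summary": summary,
                    "grid": grid_table})
    return results
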