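"""Statistics for probe-tone rating data.

Covers the full behavioral analysis of the uncertainty experiment: the
inferred-uncertainty transform (normalized entropy of a listener's probe
rating distribution), per-participant model-fit correlations with Fisher's z,
Cronbach's alpha, Tukey-fence outlier exclusion, the 2x2x2 mixed-design ANOVA
(two within-participant factors, one between), its Conover-Iman
rank-transform variant, summary-statistic t tests, the 2x2 chi-square, the
Williams/Steiger test for dependent correlations, and the model-comparison
grid pitting expectation-model configurations against rule-based competitors.

The mixed ANOVA uses the within-participant contrast reduction: with 2-level
factors, every within effect is carried by one orthonormal contrast of the
four cell means per participant, and each effect F is an OLS test on the
contrast scores with the group effect-coded (Type III; identical to the
classical univariate mixed-model analysis in balanced designs, where
sphericity is trivially satisfied).  Sums of squares are reported from the
weighted orthonormal decomposition, which is exactly additive:
SS_total = sum of all effect and error SS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expectation_model import ModelConfig, NGramStore, BOTH, LTM, STM, VARIABLE
from .info_measures import (
    entropy,
    information_content,
    max_entropy,
    schmuckler_score,
)
from .ir_baseline import fit_ir_regression, predictor_table
from .stimulus_selection import StimulusSet, target_distribution

__all__ = [
    "ParticipantProfile",
    "RatingDataset",
    "FitResult",
    "UndefinedStatisticError",
    "inferred_uncertainty",
    "inferred_uncertainty_table",
    "participant_model_fit",
    "fisher_z",
    "exclude_outliers",
    "condition_means",
    "mixed_anova",
    "rank_transform_anova",
    "cronbach_alpha",
    "welch_t",
    "pooled_t",
    "chi_square_2x2",
    "williams_t",
    "model_comparison_grid",
]

MUSICIAN, NONMUSICIAN = "musician", "non-musician"

#: Cap applied to Fisher z at |r| = 1 (atanh diverges); z is clipped to
#: atanh(1 - 1e-12), approximately 14.2.
FISHER_Z_CAP = math.atanh(1.0 - 1e-12)


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics and Gold-MSI subscale scores for one participant.

    Group membership is tied to the musical-training subscale: musicians
    scored >= 33, non-musicians <= 20.
    """

    id: str
    group: str
    age: float
    gender: str
    gmsi_training: float
    gmsi_importance: float
    gmsi_emotion: float

    def __post_init__(self) -> None:
        if self.group == MUSICIAN and self.gmsi_training < 33:
            raise ValueError(f"{self.id}: musicians require training >= 33")
        if self.group == NONMUSICIAN and self.gmsi_training > 20:
            raise ValueError(f"{self.id}: non-musicians require training <= 20")


@dataclass
class RatingDataset:
    """Tidy rating tables from (or emulating) the two experimental phases.

    ``unexpectedness``: participant x context x probe integer ratings 1-9
    (1 = highly expected); ``explicit``: participant x context explicit
    uncertainty 1-9 (1 = highly certain); ``familiarity``: participant x
    context booleans; ``profiles``: one row per participant.
    """

    unexpectedness: pd.DataFrame  # participant, context, probe, rating
    explicit: pd.DataFrame        # participant, context, rating
    familiarity: pd.DataFrame     # participant, context, familiar
    profiles: pd.DataFrame        # participant, group, age, gender, gmsi_*

    def __post_init__(self) -> None:
        for frame, col in ((self.unexpectedness, "rating"),
                           (self.explicit, "rating")):
            vals = frame[col]
            if not ((vals >= 1) & (vals <= 9)).all():
                raise ValueError("ratings must be integers in 1..9")

    def group_of(self) -> pd.Series:
        return self.profiles.set_index("participant")["group"]

    def without_familiar(self) -> "RatingDataset":
        """Drop every (participant, context) cell flagged familiar."""
        fam = self.familiarity
        bad = set(map(tuple, fam.loc[fam["familiar"],
                                     ["participant", "context"]].values))
        if not bad:
            return self

        def keep(frame: pd.DataFrame) -> pd.DataFrame:
            mask = [
                (p, c) not in bad
                for p, c in zip(frame["participant"], frame["context"])
            ]
            return frame.loc[mask].reset_index(drop=True)

        return RatingDataset(
            unexpectedness=keep(self.unexpectedness),
            explicit=keep(self.explicit),
            familiarity=fam.loc[~fam["familiar"]].reset_index(drop=True),
            profiles=self.profiles,
        )

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.unexpectedness.to_csv(directory / "unexpectedness.csv", index=False)
        self.explicit.to_csv(directory / "explicit.csv", index=False)
        self.familiarity.to_csv(directory / "familiarity.csv", index=False)
        self.profiles.to_csv(directory / "participants.csv", index=False)

    @classmethod
    def load(cls, directory) -> "RatingDataset":
        from pathlib import Path

        directory = Path(directory)
        return cls(
            unexpectedness=pd.read_csv(directory / "unexpectedness.csv"),
            explicit=pd.read_csv(directory / "explicit.csv"),
            familiarity=pd.read_csv(directory / "familiarity.csv"),
            profiles=pd.read_csv(directory / "participants.csv"),
        )


@dataclass(frozen=True)
class FitResult:
    """A model-fit correlation with its Fisher transform."""

    r: float
    z: float
    method: str
    n: int


def fisher_z(r: float) -> float:
    """atanh(r), clipped to +/-FISHER_Z_CAP so |r| = 1 stays finite."""
    return float(np.clip(math.atanh(np.clip(r, -1.0, 1.0) * (1 - 1e-15)),
                         -FISHER_Z_CAP, FISHER_Z_CAP))


# ---------------------------------------------------------------------------
# uncertainty measures from ratings
# ---------------------------------------------------------------------------


def inferred_uncertainty(probe_ratings: Sequence[float],
                         orientation: str = "raw") -> float:
    """Normalized entropy of a listener's probe-rating distribution.

    ``raw`` treats the unexpectedness ratings themselves as weights;
    ``reversed`` uses 10 - rating (expectedness).  Weights are normalized to
    a probability distribution over the nine probes and the normalized
    entropy H / log2(9) returned, in [0, 1].
    """
    r = np.asarray(probe_ratings, dtype=float)
    if np.any((r < 1) | (r > 9)):
        raise ValueError("probe ratings must lie in 1..9")
    if orientation == "raw":
        w = r
    elif orientation == "reversed":
        w = 10.0 - r
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    p = w / w.sum()
    h = -np.sum(p * np.log2(p))
    return float(h / max_entropy(len(p)))


def inferred_uncertainty_table(ratings: RatingDataset,
                               orientation: str = "raw") -> pd.DataFrame:
    """Per (participant, context) inferred uncertainty from probe ratings."""
    rows = [
        (p, c, inferred_uncertainty(grp["rating"].to_numpy(), orientation))
        for (p, c), grp in ratings.unexpectedness.groupby(
            ["participant", "context"], sort=True)
    ]
    return pd.DataFrame(rows, columns=["participant", "context", "value"])


def participant_model_fit(participant_series: Sequence[float],
                          model_series: Sequence[float],
                          method: str = "pearson") -> FitResult:
    """Correlation between one participant's ratings and a model series."""
    x = np.asarray(participant_series, dtype=float)
    y = np.asarray(model_series, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("series must be equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance in a series")
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return FitResult(r=r, z=fisher_z(r), method=method, n=int(x.size))


# ---------------------------------------------------------------------------
# outlier exclusion
# ---------------------------------------------------------------------------


def exclude_outliers(condition_means_table: pd.DataFrame,
                     multiplier: float = 1.5
                     ) -> tuple[list, pd.DataFrame]:
    """Tukey-fence participant exclusion per condition.

    ``condition_means_table``: one row per participant, one column per
    condition (participant ids as index).  A participant is excluded when any
    condition mean falls strictly outside [Q1 - m*IQR, Q3 + m*IQR] computed
    across participants within that condition; boundary values are retained.
    Returns (retained participant ids, exclusion report).
    """
    report_rows = []
    excluded = set()
    for cond in condition_means_table.columns:
        col = condition_means_table[cond].astype(float)
        q1, q3 = np.percentile(col, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
        for pid, val in col.items():
            if val < lo or val > hi:
                excluded.add(pid)
                report_rows.append(
                    {"participant": pid, "condition": cond, "value": val,
                     "lower_fence": lo, "upper_fence": hi})
    retained = [p for p in condition_means_table.index if p not in excluded]
    report = pd.DataFrame(
        report_rows,
        columns=["participant", "condition", "value", "lower_fence",
                 "upper_fence"])
    return retained, report


def condition_means(values: pd.DataFrame, stimuli: StimulusSet,
                    groups: pd.Series) -> pd.DataFrame:
    """Per-participant cell means over the 2x2 (complexity x entropy) design.

    ``values`` is tidy (participant, context, value); contexts are mapped to
    their stimulus cell.  Returns a tidy frame (participant, group,
    complexity, entropy, value) with one row per participant and cell.
    """
    cell_of = {s.label: (s.style, s.entropy_class) for s in stimuli.stimuli}
    frame = values.copy()
    frame["complexity"] = [cell_of[c][0] for c in frame["context"]]
    frame["entropy"] = [cell_of[c][1] for c in frame["context"]]
    out = (frame.groupby(["participant", "complexity", "entropy"],
                         sort=True)["value"].mean().reset_index())
    out["group"] = out["participant"].map(groups)
    return out[["participant", "group", "complexity", "entropy", "value"]]


# ---------------------------------------------------------------------------
# mixed-design ANOVA
# ---------------------------------------------------------------------------

_EFFECT_ORDER = ("expertise", "complexity", "entropy", "complexity*entropy",
                 "complexity*expertise", "entropy*expertise",
                 "complexity*entropy*expertise")


def _ols_2group(scores: np.ndarray, coding: np.ndarray
                ) -> tuple[float, float, float, float]:
    """Intercept and slope F tests for scores ~ 1 + effect-coded group.

    Returns (F_intercept, p_intercept, F_slope, p_slope) with df (1, N-2).
    The model is saturated over the two groups, so the intercept is the
    unweighted mean of the group means (a Type III test).
    """
    n = scores.size
    X = np.column_stack([np.ones(n), coding])
    beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
    resid = scores - X @ beta
    df_resid = n - 2
    mse = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    out = []
    scale = max(1.0, float(np.abs(scores).max()))
    for j in range(2):
        if mse == 0.0:
            f = 0.0 if abs(beta[j]) < 1e-10 * scale else np.inf
        else:
            f = float(beta[j] ** 2 / (mse * xtx_inv[j, j]))
        p = float(stats.f.sf(f, 1, df_resid)) if np.isfinite(f) else 0.0
        out.extend([f, p])
    return tuple(out)  # type: ignore[return-value]


def mixed_anova(data: pd.DataFrame,
                within: tuple[str, str] = ("complexity", "entropy"),
                between: str = "group",
                value: str = "value") -> pd.DataFrame:
    """2x2x2 mixed ANOVA: two within-participant factors, one between.

    ``data`` is tidy with one row per participant and within-cell (columns:
    participant, the two within factors, the between factor, and ``value``).
    Every participant must contribute all four cells; the between factor must
    have exactly two levels.  Returns a table with F, dfs, p and the weighted
    sums of squares per effect (see module docstring for their relation).
    """
    w1, w2 = within
    pivot = data.pivot_table(index=["participant", between], columns=[w1, w2],
                             values=value, aggfunc="mean")
    if pivot.isna().any().any() or pivot.shape[1] != 4:
        raise ValueError("every participant needs all four within cells")
    levels1 = sorted(data[w1].unique())
    levels2 = sorted(data[w2].unique())
    if len(levels1) != 2 or len(levels2) != 2:
        raise ValueError("within factors must each have two levels")
    groups_here = sorted(data[between].unique())
    if len(groups_here) != 2:
        raise ValueError("between factor must have two levels")

    # cell order y11, y12, y21, y22 (levels of w1 major, w2 minor)
    cols = [(a, b) for a in levels1 for b in levels2]
    Y = pivot[cols].to_numpy(dtype=float)
    n = Y.shape[0]
    if n < 4:
        raise ValueError("need at least four participants")
    coding = np.where(
        pivot.index.get_level_values(between) == groups_here[0], 1.0, -1.0)

    # orthonormal within-participant transform
    contrasts = {
        "_mean": np.array([0.5, 0.5, 0.5, 0.5]),
        w1: np.array([-0.5, -0.5, 0.5, 0.5]),
        w2: np.array([-0.5, 0.5, -0.5, 0.5]),
        f"{w1}*{w2}": np.array([0.5, -0.5, -0.5, 0.5]),
    }

    grand = Y.mean()
    rows = []

    def weighted_parts(s: np.ndarray, about_grand: bool
                       ) -> tuple[float, float, float]:
        """(SS_effect, SS_effect_x_group, SS_error) for one contrast column."""
        ref = 2.0 * grand if about_grand else 0.0
        sbar = s.mean()
        ss_eff = n * (sbar - ref) ** 2
        ss_grp, ss_err = 0.0, 0.0
        for g in (1.0, -1.0):
            sg = s[coding == g]
            ss_grp += sg.size * (sg.mean() - sbar) ** 2
            ss_err += float(((sg - sg.mean()) ** 2).sum())
        return ss_eff, ss_grp, ss_err

    # between-participant stratum: subject means (x2 = orthonormal scale)
    s0 = Y @ contrasts["_mean"]
    _, ss_a, ss_s_a = weighted_parts(s0, about_grand=True)
    _, _, f_a, p_a = _ols_2group(s0, coding)
    rows.append((between_label := "expertise", ss_a, 1, n - 2, f_a, p_a, ss_s_a))

    # within strata
    for name in (w1, w2, f"{w1}*{w2}"):
        s = Y @ contrasts[name]
        ss_eff, ss_grp, ss_err = weighted_parts(s, about_grand=False)
        f_eff, p_eff, f_int, p_int = _ols_2group(s, coding)
        rows.append((name, ss_eff, 1, n - 2, f_eff, p_eff, ss_err))
        rows.append((f"{name}*{between_label}", ss_grp, 1, n - 2, f_int,
                     p_int, ss_err))

    table = pd.DataFrame(
        rows, columns=["effect", "SS", "df1", "df2", "F", "p", "error_SS"])
    # total SS about the grand mean, for the additivity diagnostic
    table.attrs["ss_total"] = float(((Y - grand) ** 2).sum())
    table.attrs["n_participants"] = n
    return table.set_index("effect")


def rank_transform_anova(data: pd.DataFrame,
                         within: tuple[str, str] = ("complexity", "entropy"),
                         between: str = "group",
                         value: str = "value") -> pd.DataFrame:
    """Conover-Iman rank-transform mixed ANOVA.

    Midranks are assigned over the pooled dataset (all participants and
    cells), then the parametric mixed ANOVA is applied to the ranks.
    """
    ranked = data.copy()
    ranked[value] = stats.rankdata(ranked[value].to_numpy(), method="average")
    return mixed_anova(ranked, within=within, between=between, value=value)


# ---------------------------------------------------------------------------
# classical statistics
# ---------------------------------------------------------------------------


def cronbach_alpha(matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha over a cases x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of case totals).
    For inter-individual consistency, participants are the items and stimulus
    contexts the cases.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 cases and 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError("case totals have zero variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def welch_t(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
            ) -> tuple[float, float]:
    """Welch's two-sample t from summary statistics; returns (t, df)."""
    if n1 < 2 or n2 < 2 or s1 <= 0 or s2 <= 0:
        raise ValueError("need n >= 2 and positive SDs")
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return float(t), float(df)


def pooled_t(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
             ) -> tuple[float, int]:
    """Pooled-variance two-sample t from summaries; df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2 or s1 <= 0 or s2 <= 0:
        raise ValueError("need n >= 2 and positive SDs")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), df


def chi_square_2x2(counts: np.ndarray | Sequence[Sequence[float]],
                   continuity_correction: bool = False) -> float:
    """Pearson chi-square for a 2x2 table (Yates correction off by default)."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    stat = stats.chi2_contingency(table, correction=continuity_correction)[0]
    return float(stat)


def williams_t(r12: float, r13: float, r23: float, n: int
               ) -> tuple[float, int]:
    """Williams' test for two dependent correlations sharing variable 1.

    Compares r12 against r13 given the correlation r23 between variables 2
    and 3 (Steiger's formulation of Williams' T2); returns (t, df = n - 3).
    """
    for r in (r12, r13, r23):
        if abs(r) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    detR = float(np.linalg.det(R))
    rbar = (r12 + r13) / 2.0
    denom = 2.0 * ((n - 1.0) / (n - 3.0)) * detR + rbar ** 2 * (1.0 - r23) ** 3
    t = (r12 - r13) * math.sqrt((n - 1.0) * (1.0 + r23) / denom)
    return float(t), n - 3


# ---------------------------------------------------------------------------
# model-comparison grid
# ---------------------------------------------------------------------------


def default_config_grid(include_ioi_contour: bool = False
                        ) -> list[ModelConfig]:
    """Order-bound (0-4, variable) x configuration (STM/LTM/BOTH) grid."""
    grid = []
    for cfg_name in (STM, LTM, BOTH):
        for order in (0, 1, 2, 3, 4, VARIABLE):
            grid.append(ModelConfig(order_bound=order, configuration=cfg_name,
                                    include_ioi_contour=include_ioi_contour))
    return grid


def _spearman(x: Sequence[float], y: Sequence[float]) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def model_comparison_grid(stimuli: StimulusSet, ratings: RatingDataset,
                          ltm: Optional[NGramStore] | dict,
                          configs: Sequence[ModelConfig],
                          alphabet: Sequence[int],
                          orientation: str = "raw"
                          ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Correlate each model configuration (and competitors) with the data.

    For every configuration: Spearman correlations of per-stimulus model
    entropy with mean inferred and explicit uncertainty (overall and per
    group) and of per-probe model IC with mean unexpectedness.  Competitor
    rows: Schmuckler difference scores (IC and probability variants, standard
    configuration) for the uncertainty columns, and the three-predictor IR
    regression (multiple R of its fitted values) for the unexpectedness
    column.  ``ltm`` may be a single store or a ``{style: store}`` mapping
    when the two styles use differently trained long-term models.  Returns
    the comparison table and per-row trace frames from which every
    correlation can be recomputed.
    """
    clean = ratings.without_familiar()
    groups = clean.group_of()

    inferred = inferred_uncertainty_table(clean, orientation=orientation)
    inferred = inferred.merge(groups.rename("group"), left_on="participant",
                              right_index=True)
    explicit = clean.explicit.merge(groups.rename("group"),
                                    left_on="participant", right_index=True)
    unexp = clean.unexpectedness.merge(groups.rename("group"),
                                       left_on="participant",
                                       right_index=True)

    def means_by(frame: pd.DataFrame, keys: list[str],
                 who: Optional[str]) -> pd.Series:
        sub = frame if who is None else frame[frame["group"] == who]
        return sub.groupby(keys, sort=True)["value" if "value" in frame
                                            else "rating"].mean()

    order = [s.label for s in stimuli.stimuli]
    probe_order = [(s.label, p) for s in stimuli.stimuli
                   for p in s.probe_pitches]

    rows = []
    traces: dict[str, pd.DataFrame] = {}
    standard = ModelConfig(order_bound=VARIABLE, configuration=BOTH)

    def model_series(config: ModelConfig) -> tuple[pd.Series, pd.Series,
                                                   pd.Series, pd.Series]:
        ent, sch_ic, sch_p = {}, {}, {}
        ic = {}
        for stim in stimuli.stimuli:
            key = stim.key_used[0]
            store = ltm[stim.style] if isinstance(ltm, dict) else ltm
            d = target_distribution(stim, store, key, config, alphabet)
            ent[stim.label] = entropy(d)
            sch_ic[stim.label] = schmuckler_score(d, "ic")
            sch_p[stim.label] = schmuckler_score(d, "probability")
            for probe in stim.probe_pitches:
                ic[(stim.label, probe)] = information_content(d, probe)
        return (pd.Series(ent).reindex(order),
                pd.Series(ic).reindex(probe_order),
                pd.Series(sch_ic).reindex(order),
                pd.Series(sch_p).reindex(order))

    def correlate_uncertainty(series: pd.Series) -> dict:
        out = {}
        for who, suffix in ((None, "all"), (MUSICIAN, "musicians"),
                            (NONMUSICIAN, "non_musicians")):
            inf = means_by(inferred, ["context"], who).reindex(order)
            expl = means_by(explicit, ["context"], who).reindex(order)
            out[f"entropy_vs_inferred_{suffix}"] = _spearman(series, inf)
            out[f"entropy_vs_explicit_{suffix}"] = _spearman(series, expl)
        return out

    def correlate_unexpectedness(series: pd.Series) -> dict:
        out = {}
        for who, suffix in ((None, "all"), (MUSICIAN, "musicians"),
                            (NONMUSICIAN, "non_musicians")):
            mean_u = means_by(unexp, ["context", "probe"], who
                              ).reindex(probe_order)
            out[f"ic_vs_unexpectedness_{suffix}"] = _spearman(series, mean_u)
        return out

    for config in configs:
        ent, ic, _, _ = model_series(config)
        row = {"model": config.label(), "kind": "probabilistic"}
        row.update(correlate_uncertainty(ent))
        row.update(correlate_unexpectedness(ic))
        rows.append(row)
        traces[config.label()] = pd.DataFrame(
            {"context": order, "entropy": ent.values,
             "mean_inferred": means_by(inferred, ["context"], None
                                       ).reindex(order).values,
             "mean_explicit": means_by(explicit, ["context"], None
                                       ).reindex(order).values})

    # competitors
    _, _, sch_ic, sch_p = model_series(standard)
    for series, name in ((sch_ic, "schmuckler_ic"),
                         (sch_p, "schmuckler_probability")):
        row = {"model": name, "kind": "competitor"}
        row.update(correlate_uncertainty(series))
        rows.append(row)

    preds = predictor_table(stimuli.stimuli)
    complete = preds.dropna(subset=["pitch_reversal"])
    ir_row = {"model": "ir_regression", "kind": "competitor"}
    for who, suffix in ((None, "all"), (MUSICIAN, "musicians"),
                        (NONMUSICIAN, "non_musicians")):
        mean_u = means_by(unexp, ["context", "probe"], who
                          ).reindex(probe_order).to_numpy()[complete.index]
        design = complete[["proximity", "pitch_reversal", "tonal_hierarchy"]]
        fit = fit_ir_regression(design, mean_u)
        ir_row[f"ic_vs_unexpectedness_{suffix}"] = fit.multiple_r
    rows.append(ir_row)

    table = pd.DataFrame(rows).set_index("model")
    return table, traces
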