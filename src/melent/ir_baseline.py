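"""Rule-based Implication-Realization expectation predictors.

A competing, non-probabilistic account of melodic expectation: three numeric
predictors of how expected a probe tone is after a melodic context, combined
by ordinary least squares against averaged listener ratings.

* **Pitch proximity** — expectedness falls linearly with the semitone
  distance of the probe from the last context note.
* **Pitch reversal** — a two-component code over the *implicative* interval
  (the last interval of the context) and the *realized* interval (last note
  to probe): after a large implicative leap, a change of registral direction
  scores positively and a continuation negatively; small implicative
  intervals are unscored.  A returning-proximity bonus rewards realized
  pitches landing close to the pitch that launched the leap.
* **Tonal hierarchy** — the probe's key-profile value (scale-degree fit) in
  the context's key.

The numeric codings are simplifications published after the original theory;
the exact constants are held in :data:`IR_CONSTANTS` and may be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .key_finding import load_profiles
from .viewpoints import Key

__all__ = [
    "IR_CONSTANTS",
    "proximity_score",
    "pitch_reversal_score",
    "tonal_hierarchy_score",
    "predictor_table",
    "fit_ir_regression",
    "IRRegressionResult",
]

#: Default predictor constants (documented, overridable per call).
IR_CONSTANTS = {
    # proximity: score = proximity_max - min(|probe - last|, proximity_max)
    "proximity_max": 12,
    # pitch reversal: implicative intervals of at most this size carry no
    # directional implication
    "small_interval_threshold": 6,
    "direction_reversal": 1.0,
    "direction_continuation": -1.0,
    # returning proximity: bonus when the realized pitch lands within
    # return_window semitones of the pitch that began the implicative interval
    "return_bonus": 1.5,
    "return_window": 2,
    # tonal hierarchy profile set
    "profile_set": "krumhansl_kessler",
}


def proximity_score(context_last_pitch: int, probe: int,
                    constants: dict = IR_CONSTANTS) -> float:
    """Linear pitch-proximity predictor, maximal at distance zero."""
    cap = constants["proximity_max"]
    return float(cap - min(abs(probe - context_last_pitch), cap))


def pitch_reversal_score(implicative_interval: Optional[int],
                         probe_interval: int,
                         constants: dict = IR_CONSTANTS) -> float:
    """Two-component pitch-reversal predictor.

    ``implicative_interval`` is the signed last interval of the context;
    ``probe_interval`` the signed interval from the last context note to the
    probe.  Raises ``ValueError`` when the context is too short to define an
    implicative interval (the predictor is then dropped for that context).
    """
    if implicative_interval is None:
        raise ValueError("pitch reversal undefined: context has no "
                         "implicative interval")
    impl, real = implicative_interval, probe_interval
    direction = 0.0
    if abs(impl) > constants["small_interval_threshold"] and real != 0:
        same = (impl > 0) == (real > 0)
        direction = (constants["direction_continuation"] if same
                     else constants["direction_reversal"])
    score = direction
    # registral return: realized pitch close to the origin of the leap
    if abs(impl + real) <= constants["return_window"] and impl != 0:
        score += constants["return_bonus"]
    return float(score)


def tonal_hierarchy_score(probe: int, key: Key,
                          constants: dict = IR_CONSTANTS) -> float:
    """Key-profile value of the probe's scale degree in the given key."""
    profile = load_profiles()[constants["profile_set"]][key.mode]
    return float(profile[(probe - key.tonic) % 12])


def predictor_table(contexts: Sequence, constants: dict = IR_CONSTANTS
                    ) -> pd.DataFrame:
    """Per-probe IR predictor scores for a sequence of stimulus contexts.

    Each context must expose ``melody_prefix``, ``probe_pitches`` and
    ``key_used`` (as produced by stimulus selection).  Returns a tidy frame
    with one row per (context, probe).
    """
    rows = []
    for stim in contexts:
        pitches = stim.melody_prefix.pitches
        last = pitches[-1]
        impl = pitches[-1] - pitches[-2] if len(pitches) >= 2 else None
        key = stim.key_used[0]
        for probe in stim.probe_pitches:
            rows.append({
                "context": stim.label,
                "probe": probe,
                "proximity": proximity_score(last, probe, constants),
                "pitch_reversal": (
                    np.nan if impl is None
                    else pitch_reversal_score(impl, probe - last, constants)),
                "tonal_hierarchy": tonal_hierarchy_score(probe, key, constants),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IRRegressionResult:
    coefficients: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    multiple_r: float
    r_squared: float


def fit_ir_regression(predictors: pd.DataFrame,
                      mean_ratings: Sequence[float]) -> IRRegressionResult:
    """OLS of participant-averaged ratings on the IR predictors.

    Requires complete predictor columns and more rows than predictors plus
    the intercept; a rank-deficient design raises ``ValueError``.
    """
    X = np.asarray(predictors, dtype=float)
    y = np.asarray(mean_ratings, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("predictors and ratings have different lengths")
    if np.isnan(X).any():
        raise ValueError("predictor table contains missing values")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("too few rows for the number of predictors")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    names = ["intercept"] + list(predictors.columns)
    return IRRegressionResult(
        coefficients=pd.Series(fit.params, index=names),
        fitted=np.asarray(fit.fittedvalues),
        residuals=np.asarray(fit.resid),
        multiple_r=float(np.sqrt(max(fit.rsquared, 0.0))),
        r_squared=float(fit.rsquared),
    )
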