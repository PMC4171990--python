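"""Synthetic corpora and simulated listeners.

The experiment's inputs — melodic corpora and probe-tone rating data — are
emulated with known generating structure so the whole pipeline can be run
and validated without external downloads:

* **Corpora** are sampled from first-order Markov grammars over a pitch
  alphabet, with controllable per-state conditional entropy, phrase lengths
  drawn from a range, and two rhythm styles (isochronous "simple" versus
  varied-IOI "complex").  The default pitch ranges match the study
  conditions: C4-F5 for the simple style, A3-A5 for the complex style.

* **Listeners** rate probe unexpectedness as a noisy monotone (affine,
  clipped-and-rounded) function of the model's information content on the
  9-point scale, and explicit uncertainty likewise from the model's context
  entropy.  Rating noise operationalizes expertise — "musicians" carry a
  smaller noise SD, reflecting a more accurate internal predictive model —
  plus a small lapse rate of uniformly random ratings.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .behavioral_analysis import MUSICIAN, NONMUSICIAN, RatingDataset
from .info_measures import entropy, information_content
from .melody_io import Corpus, Melody, MelodyValidationError, NoteEvent
from .stimulus_selection import StimulusSet
from .viewpoints import Key

__all__ = [
    "GrammarSpec",
    "ListenerSpec",
    "generate_markov_corpus",
    "analytic_chain_entropy",
    "graded_entropy_grammar",
    "simulate_listener_ratings",
    "default_listener_specs",
]

#: Study-condition pitch ranges by style.
SIMPLE_RANGE = (60, 77)   # C4-F5
COMPLEX_RANGE = (57, 81)  # A3-A5

_ROW_TOL = 1e-12


@dataclass(frozen=True)
class GrammarSpec:
    """A first-order Markov grammar for melody generation.

    ``transition`` is row-stochastic over ``alphabet``; ``phrase_length``
    is the inclusive range of notes per phrase; ``style`` selects rhythm
    ("isochronous": all IOIs one beat; "rhythmic": durations drawn from
    {0.5, 1, 2} beats).
    """

    alphabet: tuple[int, ...]
    transition: tuple[tuple[float, ...], ...]
    initial: tuple[float, ...]
    phrase_length: tuple[int, int] = (6, 10)
    style: str = "isochronous"
    key: Optional[Key] = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition, dtype=float)
        init = np.asarray(self.initial, dtype=float)
        m = len(self.alphabet)
        if T.shape != (m, m):
            raise MelodyValidationError("transition matrix shape mismatch")
        if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > _ROW_TOL):
            raise MelodyValidationError("transition rows must sum to 1")
        if np.any(init < 0) or abs(init.sum() - 1.0) > _ROW_TOL:
            raise MelodyValidationError("initial distribution must sum to 1")
        if self.style not in ("isochronous", "rhythmic"):
            raise MelodyValidationError(f"unknown style {self.style!r}")
        if not (1 <= self.phrase_length[0] <= self.phrase_length[1]):
            raise MelodyValidationError("invalid phrase-length range")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.transition, dtype=float)

    @property
    def melody_style(self) -> str:
        return "simple" if self.style == "isochronous" else "complex"


@dataclass(frozen=True)
class ListenerSpec:
    """A simulated rater: group label, rating noise, mapping, lapse rate.

    ``noise_sd`` is Gaussian noise added on the 9-point scale after the
    affine mapping from model IC (or entropy); ``lapse_rate`` is the
    probability a trial is answered uniformly at random.
    """

    group: str
    noise_sd: float
    lapse_rate: float = 0.02
    mapping_slope: Optional[float] = None       # None: calibrated per stimulus set
    mapping_intercept: Optional[float] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")


def default_listener_specs(noise_musician: float = 1.0,
                           noise_nonmusician: float = 2.0,
                           lapse_rate: float = 0.02) -> list[ListenerSpec]:
    """The two study groups with expertise operationalized as rating noise."""
    return [
        ListenerSpec(group=MUSICIAN, noise_sd=noise_musician,
                     lapse_rate=lapse_rate),
        ListenerSpec(group=NONMUSICIAN, noise_sd=noise_nonmusician,
                     lapse_rate=lapse_rate),
    ]


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def generate_markov_corpus(spec: GrammarSpec, n_melodies: int,
                           notes_per_melody: int,
                           seed: int | np.random.Generator = 0,
                           id_prefix: str = "syn") -> Corpus:
    """Sample a corpus of melodies from a Markov grammar.

    Each melody is a fresh walk of the chain, cut into phrases whose lengths
    are drawn uniformly from the grammar's range; phrase boundaries get a
    one-beat rest before the next phrase (so gap-based phrase inference would
    recover them).  Reproducible for a fixed seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    T = spec.matrix
    init = np.asarray(spec.initial, dtype=float)
    m = len(spec.alphabet)
    melodies = []
    for j in range(n_melodies):
        states = np.empty(notes_per_melody, dtype=int)
        states[0] = rng.choice(m, p=init)
        for i in range(1, notes_per_melody):
            states[i] = rng.choice(m, p=T[states[i - 1]])
        # phrase cut points
        starts = {0}
        pos = 0
        while True:
            pos += int(rng.integers(spec.phrase_length[0],
                                    spec.phrase_length[1] + 1))
            if pos >= notes_per_melody:
                break
            starts.add(pos)
        if spec.style == "isochronous":
            durations = np.ones(notes_per_melody)
        else:
            durations = rng.choice([0.5, 1.0, 2.0], size=notes_per_melody,
                                   p=[0.35, 0.45, 0.20])
        events = []
        onset = 0.0
        for i in range(notes_per_melody):
            if i in starts and i > 0:
                onset += 1.0  # one-beat rest separating phrases
            events.append(NoteEvent(
                pitch=spec.alphabet[states[i]], onset=onset,
                duration=float(durations[i]), phrase_start=i in starts))
            onset += float(durations[i])
        melodies.append(Melody(id=f"{id_prefix}{j:03d}", events=tuple(events),
                               style=spec.melody_style, key=spec.key,
                               source="markov-grammar"))
    return Corpus(melodies=melodies)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix."""
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    if abs(vals[idx] - 1.0) > 1e-8:
        raise MelodyValidationError("chain has no unit eigenvalue")
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    return pi


def analytic_chain_entropy(spec: GrammarSpec) -> float:
    """Stationary-averaged conditional entropy of the chain, in bits.

    H = sum_s pi(s) * H(row_s).  Requires an irreducible chain (checked via
    strong connectivity of the positive-transition graph).
    """
    T = spec.matrix
    # irreducibility: every state reachable from every other
    reach = (T > 0).astype(float)
    power = np.linalg.matrix_power(reach + np.eye(len(reach)), len(reach))
    if np.any(power == 0):
        raise MelodyValidationError("chain is reducible")
    pi = stationary_distribution(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(T > 0, np.log2(np.where(T > 0, T, 1.0)), 0.0)
    row_h = -(T * logs).sum(axis=1)
    return float(pi @ row_h)


def graded_entropy_grammar(pitch_range: tuple[int, int],
                           style: str = "isochronous",
                           concentration_low: float = 0.05,
                           concentration_high: float = 12.0,
                           phrase_length: tuple[int, int] = (6, 10),
                           key: Optional[Key] = None,
                           seed: int | np.random.Generator = 0) -> GrammarSpec:
    """A grammar whose states span near-deterministic to near-uniform rows.

    Rows are Dirichlet draws with per-state concentration interpolated
    log-linearly from ``concentration_low`` (spiky rows: low conditional
    entropy) to ``concentration_high`` (flat rows: high conditional entropy),
    then floored so the chain stays irreducible.  Melodies from such a
    grammar traverse both low- and high-entropy regimes, which is what the
    entropy-extreme stimulus selection needs.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    alphabet = tuple(range(pitch_range[0], pitch_range[1] + 1))
    m = len(alphabet)
    conc = np.exp(np.linspace(np.log(concentration_low),
                              np.log(concentration_high), m))
    rows = np.empty((m, m))
    for i in range(m):
        row = rng.dirichlet(np.full(m, conc[i]))
        row = row + 1e-4  # irreducibility floor
        rows[i] = row / row.sum()
    initial = np.full(m, 1.0 / m)
    return GrammarSpec(alphabet=alphabet, transition=tuple(map(tuple, rows)),
                       initial=tuple(initial), phrase_length=phrase_length,
                       style=style, key=key)


# ---------------------------------------------------------------------------
# listener simulation
# ---------------------------------------------------------------------------


def _calibrated_mapping(values: np.ndarray) -> tuple[float, float]:
    """Affine map sending the 5th/95th percentiles of ``values`` to 1 and 9.

    Mirrors the instruction to raters to use the full range of the scale.
    """
    lo, hi = np.percentile(values, [5, 95])
    if hi - lo < 1e-9:
        return 0.0, 5.0
    slope = 8.0 / (hi - lo)
    return float(slope), float(1.0 - slope * lo)


def _rate(x: np.ndarray, slope: float, intercept: float, noise_sd: float,
          lapse_rate: float, rng: np.random.Generator) -> np.ndarray:
    raw = slope * x + intercept + rng.normal(0.0, noise_sd, size=x.shape)
    ratings = np.clip(np.rint(raw), 1, 9).astype(int)
    lapses = rng.random(x.shape) < lapse_rate
    ratings[lapses] = rng.integers(1, 10, size=int(lapses.sum()))
    return ratings


def simulate_listener_ratings(stimuli: StimulusSet,
                              model_ic: pd.DataFrame,
                              model_entropy: pd.Series,
                              listeners: Sequence[ListenerSpec],
                              n_per_group: int = 17,
                              seed: int | np.random.Generator = 0,
                              familiar_rate: float = 0.0) -> RatingDataset:
    """Simulate the two experimental phases for groups of listeners.

    ``model_ic``: tidy frame (context, probe, ic) per probe trial;
    ``model_entropy``: per-context entropy series (index = context labels).
    Unexpectedness ratings are clip-and-rounded affine transforms of IC plus
    listener noise; explicit uncertainty likewise from entropy.  Gold-MSI
    profiles are drawn per group around the study's summary statistics.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    contexts = [s.label for s in stimuli.stimuli]
    if set(model_entropy.index) != set(contexts):
        raise MelodyValidationError("model entropy misaligned with stimuli")
    if set(model_ic["context"]) != set(contexts):
        raise MelodyValidationError("model IC misaligned with stimuli")

    ic_vals = model_ic["ic"].to_numpy(dtype=float)
    ent_vals = model_entropy.reindex(contexts).to_numpy(dtype=float)
    ic_slope, ic_icept = _calibrated_mapping(ic_vals)
    en_slope, en_icept = _calibrated_mapping(ent_vals)

    unexp_rows, expl_rows, fam_rows, prof_rows = [], [], [], []
    pid = 0
    for spec in listeners:
        slope = spec.mapping_slope
        for _ in range(n_per_group):
            pid += 1
            name = f"P{pid:03d}"
            u = _rate(ic_vals,
                      ic_slope if slope is None else slope,
                      ic_icept if spec.mapping_intercept is None
                      else spec.mapping_intercept,
                      spec.noise_sd, spec.lapse_rate, rng)
            for (ctx, probe), rating in zip(
                    zip(model_ic["context"], model_ic["probe"]), u):
                unexp_rows.append((name, ctx, int(probe), int(rating)))
            e = _rate(ent_vals,
                      en_slope if slope is None else slope,
                      en_icept if spec.mapping_intercept is None
                      else spec.mapping_intercept,
                      spec.noise_sd, spec.lapse_rate, rng)
            for ctx, rating in zip(contexts, e):
                expl_rows.append((name, ctx, int(rating)))
            for ctx in contexts:
                fam_rows.append((name, ctx,
                                 bool(rng.random() < familiar_rate)))
            if spec.group == MUSICIAN:
                training = float(np.clip(rng.normal(53.12, 7.83), 33, 63))
            else:
                training = float(np.clip(rng.normal(13.94, 3.56), 7, 20))
            prof_rows.append((
                name, spec.group,
                float(np.clip(rng.normal(27.8, 6.0), 18, 60)),
                "female" if rng.random() < 0.5 else "male",
                training,
                float(np.clip(rng.normal(35.0, 8.0), 7, 63)),
                float(np.clip(rng.normal(30.0, 7.0), 6, 56)),
            ))

    return RatingDataset(
        unexpectedness=pd.DataFrame(
            unexp_rows, columns=["participant", "context", "probe", "rating"]),
        explicit=pd.DataFrame(
            expl_rows, columns=["participant", "context", "rating"]),
        familiarity=pd.DataFrame(
            fam_rows, columns=["participant", "context", "familiar"]),
        profiles=pd.DataFrame(
            prof_rows, columns=["participant", "group", "age", "gender",
                                "gmsi_training", "gmsi_importance",
                                "gmsi_emotion"]),
    )
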