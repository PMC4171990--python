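"""Variable-order Markov expectation model with PPM-style smoothing.

The model predicts the pitch of the next note in a monophonic melody from
n-gram statistics over linked viewpoint symbols (pitch interval x scale degree
[x IOI contour], see :mod:`melent.viewpoints`).  Three features beyond a basic
fixed-order Markov model:

* **Smoothing.**  Predictions blend maximum-likelihood estimates from the
  longest matching context down to order 0, with escape probabilities
  (method C by default: Witten-Bell) passing mass to shorter contexts and a
  uniform floor over the alphabet terminating the recursion.  Every symbol
  therefore receives strictly positive probability.  An order bound may be
  fixed (0-4) or *variable*, in which case the longest context with support
  is used (PPM*-like).

* **Two sub-models.**  A *long-term* sub-model (LTM) is trained on a corpus
  beforehand, modelling schematic, enculturated expectation; a *short-term*
  sub-model (STM) starts empty for each melody and learns online, modelling
  within-piece regularities.  When both are active their distributions are
  combined by an entropy-weighted geometric mean: the sub-model that is more
  confident (lower normalized entropy) receives more weight, with the bias
  exponent ``b`` controlling how strongly.

* **Viewpoint linkage.**  Candidate pitches are mapped to derived symbols
  (injectively, given the previous pitch and key), predicted in symbol space
  and mapped back, so the model benefits from transposition-invariant
  statistics while still emitting distributions over concrete pitches.

The first event of a melody has no pitch interval; it is represented (and
predicted) by a scale-degree-only symbol through the same counting and
smoothing path, so candidates an octave apart share a first-event symbol and
split its probability mass evenly after renormalization.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .info_measures import PredictiveDistribution, normalized_entropy
from .key_finding import estimate_key
from .melody_io import Corpus, Melody, MelodyValidationError
from .viewpoints import Key, ViewpointSymbol, derive_viewpoints, symbol_for_candidate

__all__ = [
    "ModelConfig",
    "NGramStore",
    "PredictiveDistribution",
    "train_ltm",
    "ppm_probability",
    "ppm_distribution",
    "predict_next",
    "combine_distributions",
    "sequence_predictions",
    "build_alphabet",
]

VARIABLE = None  # sentinel: no fixed order bound

#: Practical cap on stored context length under the variable-order strategy.
#: Melodic contexts longer than this essentially never recur in corpora of the
#: sizes used here; the cap bounds memory without changing predictions.
VARIABLE_ORDER_CAP = 10

STM, LTM, BOTH = "STM", "LTM", "BOTH"

_ESCAPE_METHODS = ("A", "C", "D")
_MIN_HNORM = 1e-6  # floor for entropy-based combination weights


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the expectation model.

    ``order_bound`` is the maximum context length (``None`` = variable order);
    ``configuration`` selects the active sub-models; ``combination_bias`` is
    the exponent ``b`` weighting lower-entropy sub-models more strongly.
    ``alphabet_policy`` is either ``"corpus"`` (pitches observed in training
    plus the stimulus) or ``"chromatic_span"`` (chromatic fill of the corpus
    range, reproducing e.g. a 37-pitch B2-B5 span).
    """

    order_bound: Optional[int] = VARIABLE
    configuration: str = BOTH
    escape_method: str = "C"
    update_exclusion: bool = True
    combination_bias: float = 1.0
    include_ioi_contour: bool = False
    alphabet_policy: str = "corpus"
    smoothing: str = "interpolated"

    def __post_init__(self) -> None:
        if self.order_bound is not None and self.order_bound < 0:
            raise ValueError("order_bound must be >= 0 or None (variable)")
        if self.configuration not in (STM, LTM, BOTH):
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.escape_method not in _ESCAPE_METHODS:
            raise ValueError(f"unknown escape method {self.escape_method!r}")
        if self.smoothing not in ("interpolated", "backoff"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")
        if self.combination_bias < 0:
            raise ValueError("combination_bias must be non-negative")

    @property
    def max_stored_order(self) -> int:
        if self.order_bound is VARIABLE:
            return VARIABLE_ORDER_CAP
        return self.order_bound

    def label(self) -> str:
        order = "var" if self.order_bound is VARIABLE else str(self.order_bound)
        return f"{self.configuration}-order{order}"


class NGramStore:
    """Context -> next-symbol counts for all context lengths up to a bound.

    The trainable state of one sub-model.  ``counts`` maps context tuples
    (length 0..max_order) to Counters over next symbols.  Melody-initial
    events are counted as their scale-degree-only symbols, so first-event
    predictions flow through the same smoothing path as every other
    prediction.  Counts are consistent by construction: the total count of
    continuations of a context equals the number of times the context was
    followed by anything.
    """

    def __init__(self, max_order: int = VARIABLE_ORDER_CAP) -> None:
        self.max_order = max_order
        self.counts: dict[tuple, Counter] = {}
        self.n_sequences = 0

    # -- training ----------------------------------------------------------

    def add_event(self, seq: Sequence[ViewpointSymbol], i: int,
                  update_exclusion: bool = True) -> None:
        """Record symbol ``seq[i]`` with its preceding contexts.

        With update exclusion, counts are updated from the longest available
        context down until (and including) the first context in which the
        symbol had already been seen; shorter contexts keep their counts, as
        the longer context would have predicted the symbol on its own.
        """
        s = seq[i]
        longest = min(i, self.max_order)
        for k in range(longest, -1, -1):
            ctx = tuple(seq[i - k:i])
            counter = self.counts.setdefault(ctx, Counter())
            previously_seen = counter[s] > 0
            counter[s] += 1
            if update_exclusion and previously_seen:
                break

    def add_sequence(self, symbols: Sequence[ViewpointSymbol],
                     update_exclusion: bool = True) -> None:
        """Train on one melody's symbol sequence (restarting the context).

        Contexts never span a melody boundary; the first symbol (which lacks
        a pitch interval) is counted like any other.
        """
        seq = list(symbols)
        for i in range(len(seq)):
            self.add_event(seq, i, update_exclusion=update_exclusion)
        self.n_sequences += 1

    # -- queries -----------------------------------------------------------

    def context_stats(self, ctx: tuple) -> tuple[int, int, Counter]:
        """(total count n, distinct continuations t, counter) for a context."""
        counter = self.counts.get(ctx)
        if not counter:
            return 0, 0, Counter()
        n = sum(counter.values())
        return n, len(counter), counter

    def total_events(self) -> int:
        return sum(self.counts.get((), Counter()).values())

    # -- persistence -------------------------------------------------------

    @staticmethod
    def _sym_to_list(s: ViewpointSymbol) -> list:
        return [s.pitch_interval, s.scale_degree, s.ioi_contour]

    @staticmethod
    def _sym_from_list(lst: list) -> ViewpointSymbol:
        return ViewpointSymbol(pitch_interval=lst[0], scale_degree=lst[1],
                               ioi_contour=lst[2])

    def to_json(self) -> dict:
        entries = []
        for ctx, counter in self.counts.items():
            entries.append({
                "context": [self._sym_to_list(s) for s in ctx],
                "continuations": [
                    [self._sym_to_list(s), c] for s, c in sorted(
                        counter.items(), key=lambda kv: str(kv[0]))
                ],
            })
        return {
            "format": "melent-ngram-store",
            "version": 1,
            "max_order": self.max_order,
            "n_sequences": self.n_sequences,
            "counts": entries,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "NGramStore":
        store = cls(max_order=payload["max_order"])
        store.n_sequences = payload.get("n_sequences", 0)
        for entry in payload["counts"]:
            ctx = tuple(cls._sym_from_list(s) for s in entry["context"])
            counter = Counter()
            for sym, c in entry["continuations"]:
                counter[cls._sym_from_list(sym)] = int(c)
            store.counts[ctx] = counter
        return store

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "NGramStore":
        return cls.from_json(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def melody_key(melody: Melody) -> Key:
    """The melody's stored key, or an estimated one if absent."""
    return melody.key if melody.key is not None else estimate_key(melody)


def train_ltm(corpus: Corpus, config: ModelConfig) -> NGramStore:
    """Train the long-term sub-model over every melody of a corpus.

    Each melody is rendered as a viewpoint symbol sequence under its own key
    (stored or estimated) and counted with per-melody context restarts.
    Deterministic: depends only on the corpus content and order.
    """
    if not corpus.melodies:
        raise MelodyValidationError("cannot train on an empty corpus")
    store = NGramStore(max_order=config.max_stored_order)
    for melody in corpus.melodies:
        include_ioi = config.include_ioi_contour and melody.style == "complex"
        symbols = derive_viewpoints(melody, melody_key(melody),
                                    include_ioi_contour=include_ioi)
        store.add_sequence(symbols, update_exclusion=config.update_exclusion)
    return store


# ---------------------------------------------------------------------------
# PPM smoothing
# ---------------------------------------------------------------------------


def _escape_terms(n: int, t: int, count: int, method: str) -> tuple[float, float]:
    """(maximum-likelihood contribution of a symbol, escape weight gamma)."""
    if method == "C":  # Witten-Bell
        return count / (n + t), t / (n + t)
    if method == "A":
        return count / (n + 1), 1.0 / (n + 1)
    if method == "D":
        return (count - 0.5) / n if count > 0 else 0.0, t / (2.0 * n)
    raise ValueError(f"unknown escape method {method!r}")


def _context_chain(store: NGramStore, context: tuple,
                   config: ModelConfig) -> list[tuple]:
    """Context suffixes from longest usable down to the empty context."""
    if config.order_bound is VARIABLE:
        start = min(len(context), store.max_order)
        # variable order: begin at the longest suffix with support
        while start > 0 and context[len(context) - start:] not in store.counts:
            start -= 1
    else:
        start = min(len(context), config.order_bound, store.max_order)
    return [context[len(context) - k:] for k in range(start, -1, -1)]


def ppm_distribution(store: NGramStore, context: tuple,
                     alphabet: Sequence[ViewpointSymbol],
                     config: ModelConfig) -> np.ndarray:
    """Smoothed probability vector over a symbol alphabet given a context.

    Interpolated smoothing blends maximum-likelihood estimates at each context
    length with the escape-weighted distribution of the next shorter context,
    bottoming out at the uniform distribution; backoff smoothing instead gives
    escape mass only to symbols unseen at the longer context.  Both yield a
    strictly positive vector summing to one.
    """
    if not alphabet:
        raise MelodyValidationError("symbol alphabet is empty")
    symbols = list(alphabet)
    m = len(symbols)
    chain = _context_chain(store, tuple(context), config)  # longest .. empty
    p = np.full(m, 1.0 / m)  # uniform floor terminates the recursion
    for ctx in reversed(chain):  # build upward from short to long contexts
        n, t, counter = store.context_stats(ctx)
        if n == 0:
            continue  # unseen context: escape with certainty
        ml = np.empty(m)
        gamma = 0.0
        for j, s in enumerate(symbols):
            ml[j], gamma = _escape_terms(n, t, counter.get(s, 0), config.escape_method)
        if config.smoothing == "interpolated":
            p = ml + gamma * p
        else:  # backoff: lower-order mass only for locally unseen symbols
            unseen = np.array([counter.get(s, 0) == 0 for s in symbols])
            new = ml.copy()
            lower_mass = p[unseen].sum()
            if unseen.any() and lower_mass > 0:
                new[unseen] = gamma * p[unseen] / lower_mass
            p = new
    # the alphabet need not exhaust the continuations seen in training, so the
    # recursion can leave a small deficit; normalize once at the end
    return p / p.sum()


def ppm_probability(store: NGramStore, context: tuple, symbol: ViewpointSymbol,
                    alphabet: Sequence[ViewpointSymbol],
                    config: ModelConfig) -> float:
    """Smoothed probability of one symbol; see :func:`ppm_distribution`."""
    symbols = list(alphabet)
    if symbol not in symbols:
        raise MelodyValidationError("queried symbol not in alphabet")
    p = ppm_distribution(store, context, symbols, config)
    return float(p[symbols.index(symbol)])


# ---------------------------------------------------------------------------
# prediction over pitch alphabets
# ---------------------------------------------------------------------------


def build_alphabet(corpus: Corpus, policy: str = "corpus",
                   extra: Iterable[int] = ()) -> tuple[int, ...]:
    """Pitch alphabet for prediction under the configured policy.

    ``"corpus"``: sorted union of corpus pitches and ``extra``;
    ``"chromatic_span"``: every chromatic pitch between the extremes of that
    union (a corpus spanning B2-B5 yields the 37-pitch alphabet).
    """
    pitches = set(corpus.alphabet) | set(extra)
    if policy == "corpus":
        return tuple(sorted(pitches))
    if policy == "chromatic_span":
        return tuple(range(min(pitches), max(pitches) + 1))
    raise ValueError(f"unknown alphabet policy {policy!r}")


def combine_distributions(d1: PredictiveDistribution, d2: PredictiveDistribution,
                          b: float = 1.0) -> PredictiveDistribution:
    """Entropy-weighted geometric mean of two predictive distributions.

    Weights are ``w_i = H_norm(d_i) ** -b`` so the lower-entropy (more
    confident) sub-model dominates as ``b`` grows; ``b = 0`` gives the plain
    geometric mean.  The result is renormalized over the shared alphabet.
    """
    if d1.alphabet != d2.alphabet:
        raise MelodyValidationError("cannot combine distributions over "
                                    "different alphabets")
    if b < 0:
        raise ValueError("bias b must be non-negative")
    w1 = max(normalized_entropy(d1), _MIN_HNORM) ** -b
    w2 = max(normalized_entropy(d2), _MIN_HNORM) ** -b
    log_p = (w1 * np.log(d1.p) + w2 * np.log(d2.p)) / (w1 + w2)
    p = np.exp(log_p - log_p.max())
    p /= p.sum()
    return PredictiveDistribution(
        alphabet=d1.alphabet, p=p,
        provenance={"combined": [d1.provenance, d2.provenance], "bias": b},
    )


def predict_next(ltm: Optional[NGramStore], stm: Optional[NGramStore],
                 context_melody: Melody | None, key: Key,
                 alphabet: Sequence[int], config: ModelConfig,
                 next_onset: Optional[float] = None) -> PredictiveDistribution:
    """Predictive distribution over candidate pitches for the next event.

    ``context_melody`` is the melodic prefix heard so far (``None`` or empty
    for a first-event prediction).  ``next_onset`` supplies the onset of the
    event under prediction so the IOI-contour component of candidate symbols
    can be formed; when unavailable the contour is left undefined.
    """
    if not alphabet:
        raise MelodyValidationError("pitch alphabet is empty")
    stores: list[NGramStore] = []
    if config.configuration in (LTM, BOTH):
        if ltm is None:
            raise MelodyValidationError("configuration requires an LTM store")
        stores.append(ltm)
    if config.configuration in (STM, BOTH):
        if stm is None:
            raise MelodyValidationError("configuration requires an STM store")
        stores.append(stm)

    if context_melody is None or len(context_melody) == 0:
        # first event: scale-degree-only candidate symbols, empty context
        # (octave-related candidates share a symbol and split its mass)
        first_symbols = [symbol_for_candidate(None, a, key) for a in alphabet]
        parts0 = [
            PredictiveDistribution(
                alphabet=tuple(alphabet),
                p=ppm_distribution(store, (), first_symbols, config),
                provenance={"position": 0, "config": config.label()},
            )
            for store in stores
        ]
        if len(parts0) == 1:
            return parts0[0]
        return combine_distributions(parts0[0], parts0[1],
                                     b=config.combination_bias)

    include_ioi = config.include_ioi_contour and context_melody.style == "complex"
    symbols = derive_viewpoints(context_melody, key,
                                include_ioi_contour=include_ioi)
    context = tuple(symbols)

    contour = None
    if include_ioi and len(context_melody) >= 2 and next_onset is not None:
        onsets = [e.onset for e in context_melody.events]
        ioi_next = next_onset - onsets[-1]
        ioi_prev = onsets[-1] - onsets[-2]
        contour = (ioi_next > ioi_prev) - (ioi_next < ioi_prev)

    last_pitch = context_melody.pitches[-1]
    candidate_symbols = [
        symbol_for_candidate(last_pitch, a, key, ioi_contour=contour)
        for a in alphabet
    ]

    parts = [
        PredictiveDistribution(
            alphabet=tuple(alphabet),
            p=ppm_distribution(store, context, candidate_symbols, config),
            provenance={"submodel": name, "config": config.label()},
        )
        for store, name in zip(stores, ([LTM, STM] if len(stores) == 2
                                        else [config.configuration]))
    ]
    if len(parts) == 1:
        return parts[0]
    return combine_distributions(parts[0], parts[1], b=config.combination_bias)


def sequence_predictions(melody: Melody, ltm: Optional[NGramStore], key: Key,
                         config: ModelConfig,
                         alphabet: Sequence[int]) -> list[PredictiveDistribution]:
    """Per-note predictive distributions over a melody.

    The STM (when active) starts empty and is updated with each observed note
    *after* that note has been predicted, so every prediction is causal.
    """
    if len(melody) == 0:
        raise MelodyValidationError("melody is empty")
    include_ioi = config.include_ioi_contour and melody.style == "complex"
    symbols = derive_viewpoints(melody, key, include_ioi_contour=include_ioi)
    stm = (NGramStore(max_order=config.max_stored_order)
           if config.configuration in (STM, BOTH) else None)
    out = []
    for i in range(len(melody)):
        prefix = melody.prefix(i) if i > 0 else None
        out.append(
            predict_next(ltm, stm, prefix, key, alphabet, config,
                         next_onset=melody.events[i].onset)
        )
        if stm is not None:  # observe the note the prediction was about
            stm.add_event(symbols, i,
                          update_exclusion=config.update_exclusion)
    return out
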