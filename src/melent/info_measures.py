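"""Information-theoretic summaries of predictive distributions.

All logarithms are base 2; information content and entropy are in bits.
For a distribution p over an alphabet of n events:

* information content  IC(x) = -log2 p(x) — the surprisal of event x;
* entropy              H = -sum p(x) log2 p(x) — expected IC, the model's
  predictive uncertainty before the event;
* maximum entropy      H_max = log2 n (the uniform distribution);
* normalized entropy   H_norm = H / H_max, comparable across alphabet sizes.

Also provided: restriction of a distribution to a pitch subset (the 9-tone
renormalization used in stimulus selection) and the Schmuckler difference
score, a coarse non-probabilistic competitor to entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PredictiveDistribution",
    "information_content",
    "entropy",
    "max_entropy",
    "normalized_entropy",
    "renormalize_subset",
    "schmuckler_score",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PredictiveDistribution:
    """A strictly positive probability distribution over an ordered pitch list.

    ``provenance`` records how the distribution was produced (model
    configuration, context reference); it does not affect equality of the
    numeric content.
    """

    alphabet: tuple[int, ...]
    p: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if len(self.alphabet) != p.shape[0]:
            raise ValueError("alphabet and probability vector lengths differ")
        if np.any(p <= 0):
            raise ValueError("probabilities must be strictly positive")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")

    def probability(self, x: int) -> float:
        try:
            return float(self.p[self.alphabet.index(x)])
        except ValueError:
            raise KeyError(f"pitch {x} not in alphabet") from None

    @property
    def n(self) -> int:
        return len(self.alphabet)

    def argmax_pitch(self) -> int:
        return self.alphabet[int(np.argmax(self.p))]


def information_content(d: PredictiveDistribution, x: int) -> float:
    """IC(x) = -log2 p(x), in bits; finite since p is strictly positive."""
    return -float(np.log2(d.probability(x)))


def entropy(d: PredictiveDistribution) -> float:
    """H = -sum p log2 p, in bits; lies in [0, log2 n]."""
    return -float(np.sum(d.p * np.log2(d.p)))


def max_entropy(n: int) -> float:
    """log2 n — entropy of the uniform distribution over n events."""
    if n < 1:
        raise ValueError(f"alphabet size must be >= 1, got {n}")
    return float(np.log2(n))


def normalized_entropy(d: PredictiveDistribution) -> float:
    """H / log2 n, dimensionless in [0, 1]; undefined for n = 1."""
    if d.n < 2:
        raise ValueError("normalized entropy undefined for a 1-event alphabet")
    return entropy(d) / max_entropy(d.n)


def renormalize_subset(d: PredictiveDistribution,
                       subset: Sequence[int]) -> PredictiveDistribution:
    """Restrict to a pitch subset and rescale to sum one.

    Output ordering follows ``subset``.  Used for the 9-tone entropy of
    stimulus selection: the full-alphabet distribution is renormalized over
    the nine probe pitches.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    p = np.array([d.probability(x) for x in subset])
    return PredictiveDistribution(
        alphabet=subset, p=p / p.sum(),
        provenance={**d.provenance, "subset_of": d.n},
    )


def schmuckler_score(d: PredictiveDistribution, variant: str = "ic") -> float:
    """Mean-minus-minimum difference score over a predictive distribution.

    ``variant="ic"``: mean(IC) - min(IC) over the alphabet;
    ``variant="probability"``: mean(p) - min(p).  Both are >= 0 and zero only
    for the uniform distribution.  A flatness summary used as a
    non-entropy competitor for modelling uncertainty.
    """
    if variant == "ic":
        ic = -np.log2(d.p)
        return max(float(ic.mean() - ic.min()), 0.0)  # clamp float round-off
    if variant == "probability":
        return max(float(d.p.mean() - d.p.min()), 0.0)
    raise ValueError(f"unknown variant {variant!r}")
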