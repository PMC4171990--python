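"""Independent brute-force oracles used by the test suite.

These re-implement, from their published definitions and with exact rational
arithmetic where possible, the quantities the library computes numerically:
the PPM escape recursion, the balanced mixed-design ANOVA cell-means
decomposition, and the Williams/Steiger dependent-correlation statistic.
They deliberately share no code with the implementations they check.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# PPM escape recursion (exact, rational)
# ---------------------------------------------------------------------------


def ppm_oracle(counts: dict, context: tuple, alphabet: list,
               escape: str = "C", order_bound=None, max_order: int = 10,
               smoothing: str = "interpolated") -> dict:
    """Exact smoothed distribution over ``alphabet`` by symbolic recursion.

    ``counts`` maps context tuples to {symbol: count}.  Returns
    {symbol: Fraction} normalized over the alphabet.  Interpolated smoothing:
    p_k(s) = ml_k(s) + gamma_k * p_{k-1}(s), grounded in uniform 1/|A|;
    backoff gives lower-order mass only to symbols unseen at order k.
    """
    context = tuple(context)

    def stats(ctx):
        counter = counts.get(ctx, {})
        n = sum(counter.values())
        t = len([s for s in counter if counter[s] > 0])
        return n, t, counter

    def terms(n, t, c):
        if escape == "C":
            return Fraction(c, n + t), Fraction(t, n + t)
        if escape == "A":
            return Fraction(c, n + 1), Fraction(1, n + 1)
        if escape == "D":
            return (Fraction(2 * c - 1, 2 * n) if c > 0 else Fraction(0),
                    Fraction(t, 2 * n))
        raise ValueError(escape)

    # longest usable context suffix
    if order_bound is None:
        start = min(len(context), max_order)
        while start > 0:
            ctx = context[len(context) - start:]
            if stats(ctx)[0] > 0:
                break
            start -= 1
    else:
        start = min(len(context), order_bound, max_order)

    m = len(alphabet)

    def recurse(k):
        if k < 0:
            return {s: Fraction(1, m) for s in alphabet}
        ctx = context[len(context) - k:]
        n, t, counter = stats(ctx)
        lower = recurse(k - 1)
        if n == 0:
            return lower
        out = {}
        if smoothing == "interpolated":
            for s in alphabet:
                ml, gamma = terms(n, t, counter.get(s, 0))
                out[s] = ml + gamma * lower[s]
        else:
            unseen = [s for s in alphabet if counter.get(s, 0) == 0]
            lower_mass = sum(lower[s] for s in unseen)
            for s in alphabet:
                ml, gamma = terms(n, t, counter.get(s, 0))
                if counter.get(s, 0) > 0:
                    out[s] = ml
                elif lower_mass > 0:
                    out[s] = gamma * lower[s] / lower_mass
                else:
                    out[s] = Fraction(0)
        return out

    raw = recurse(start)
    total = sum(raw[s] for s in alphabet)
    return {s: raw[s] / total for s in alphabet}


# ---------------------------------------------------------------------------
# balanced 2x2x2 mixed ANOVA by cell-means decomposition
# ---------------------------------------------------------------------------


def mixed_anova_oracle(data: pd.DataFrame, within=("complexity", "entropy"),
                       between="group", value="value") -> pd.DataFrame:
    """Textbook sums-of-squares decomposition for a *balanced* design.

    Returns a table with SS, df and F per effect, using participants-within-
    groups as the between error and effect-by-subject interactions as the
    within errors.
    """
    w1, w2 = within
    d = data.copy()
    subs = sorted(d["participant"].unique())
    groups = sorted(d[between].unique())
    l1 = sorted(d[w1].unique())
    l2 = sorted(d[w2].unique())
    n_per = {g: d[d[between] == g]["participant"].nunique() for g in groups}
    assert len(set(n_per.values())) == 1, "oracle requires a balanced design"
    N = len(subs)

    def mean(**kw):
        sub = d
        for col, lev in kw.items():
            sub = sub[sub[col] == lev]
        return sub[value].mean()

    grand = d[value].mean()
    sub_group = d.drop_duplicates("participant").set_index(
        "participant")[between]

    ss_a = 4 * sum(n_per[g] * (mean(**{between: g}) - grand) ** 2
                   for g in groups)
    ss_sa = 4 * sum((mean(participant=p) - mean(**{between: sub_group[p]}))
                    ** 2 for p in subs)

    ss_b = 2 * N * sum((mean(**{w1: b}) - grand) ** 2 for b in l1)
    ss_c = 2 * N * sum((mean(**{w2: c}) - grand) ** 2 for c in l2)
    ss_ab = 2 * sum(n_per[g] * (mean(**{between: g, w1: b})
                                - mean(**{between: g}) - mean(**{w1: b})
                                + grand) ** 2
                    for g in groups for b in l1)
    ss_ac = 2 * sum(n_per[g] * (mean(**{between: g, w2: c})
                                - mean(**{between: g}) - mean(**{w2: c})
                                + grand) ** 2
                    for g in groups for c in l2)
    ss_bc = N * sum((mean(**{w1: b, w2: c}) - mean(**{w1: b})
                     - mean(**{w2: c}) + grand) ** 2
                    for b in l1 for c in l2)
    ss_abc = sum(n_per[g] * (mean(**{between: g, w1: b, w2: c})
                             - mean(**{between: g, w1: b})
                             - mean(**{between: g, w2: c})
                             - mean(**{w1: b, w2: c})
                             + mean(**{between: g}) + mean(**{w1: b})
                             + mean(**{w2: c}) - grand) ** 2
                 for g in groups for b in l1 for c in l2)

    ss_b_sa = 2 * sum(
        (mean(participant=p, **{w1: b}) - mean(participant=p)
         - mean(**{between: sub_group[p], w1: b})
         + mean(**{between: sub_group[p]})) ** 2
        for p in subs for b in l1)
    ss_c_sa = 2 * sum(
        (mean(participant=p, **{w2: c}) - mean(participant=p)
         - mean(**{between: sub_group[p], w2: c})
         + mean(**{between: sub_group[p]})) ** 2
        for p in subs for c in l2)
    # three-way residual: total within-cell SS minus everything else
    ss_total = ((d[value] - grand) ** 2).sum()
    ss_bc_sa = (ss_total - ss_a - ss_sa - ss_b - ss_ab - ss_b_sa
                - ss_c - ss_ac - ss_c_sa - ss_bc - ss_abc)

    df_err = N - len(groups)
    rows = [
        ("expertise", ss_a, 1, df_err, ss_sa),
        (w1, ss_b, 1, df_err, ss_b_sa),
        (f"{w1}*expertise", ss_ab, 1, df_err, ss_b_sa),
        (w2, ss_c, 1, df_err, ss_c_sa),
        (f"{w2}*expertise", ss_ac, 1, df_err, ss_c_sa),
        (f"{w1}*{w2}", ss_bc, 1, df_err, ss_bc_sa),
        (f"{w1}*{w2}*expertise", ss_abc, 1, df_err, ss_bc_sa),
    ]
    table = pd.DataFrame(rows, columns=["effect", "SS", "df1", "df2",
                                        "error_SS"])
    table["F"] = table["SS"] / (table["error_SS"] / table["df2"])
    return table.set_index("effect")


# ---------------------------------------------------------------------------
# Williams/Steiger T2 via an independent symbolic evaluation
# ---------------------------------------------------------------------------


def williams_oracle(r12: float, r13: float, r23: float, n: int) -> float:
    """Williams' T2 evaluated with sympy rationals from the published form."""
    import sympy as sp

    r12, r13, r23 = map(sp.Rational, map(str, (r12, r13, r23)))
    detR = (1 - r12 ** 2 - r13 ** 2 - r23 ** 2 + 2 * r12 * r13 * r23)
    rbar = (r12 + r13) / 2
    expr = (r12 - r13) * sp.sqrt(
        (n - 1) * (1 + r23)
        / (2 * sp.Rational(n - 1, n - 3) * detR
           + rbar ** 2 * (1 - r23) ** 3))
    return float(expr)
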