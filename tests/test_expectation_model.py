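"""Expectation model: counting, PPM oracle equivalence, combination, recovery."""

import itertools
import math

import numpy as np
import pytest

from conftest import melody_from_pitches
from melent.expectation_model import (
    BOTH,
    LTM,
    STM,
    ModelConfig,
    NGramStore,
    VARIABLE,
    build_alphabet,
    combine_distributions,
    ppm_distribution,
    ppm_probability,
    predict_next,
    sequence_predictions,
    train_ltm,
)
from melent.info_measures import PredictiveDistribution, entropy
from melent.melody_io import Corpus, MelodyValidationError
from melent.synthetic_data import (
    GrammarSpec,
    analytic_chain_entropy,
    generate_markov_corpus,
)
from melent.viewpoints import Key, ViewpointSymbol, derive_viewpoints
from oracles import ppm_oracle


def tokens(*names):
    """Distinct abstract symbols (scale degrees double as token ids)."""
    return [ViewpointSymbol(pitch_interval=1, scale_degree=ord(n) - ord("a"))
            for n in names]


A, B, C = tokens("a", "b", "c")


class TestCounting:
    def test_order1_counts(self):
        store = NGramStore(max_order=1)
        store.add_sequence([A, B, A, B, A], update_exclusion=False)
        assert store.counts[()] == {A: 3, B: 2}
        assert store.counts[(A,)] == {B: 2}
        assert store.counts[(B,)] == {A: 2}

    def test_additivity_over_copies(self):
        one = NGramStore(max_order=1)
        one.add_sequence([A, B, A, B, A], update_exclusion=False)
        two = NGramStore(max_order=1)
        two.add_sequence([A, B, A, B, A], update_exclusion=False)
        two.add_sequence([A, B, A, B, A], update_exclusion=False)
        for ctx, counter in one.counts.items():
            assert two.counts[ctx] == {s: 2 * c for s, c in counter.items()}

    def test_order2_counts(self):
        store = NGramStore(max_order=2)
        store.add_sequence([A, B, A, B, A], update_exclusion=False)
        assert store.counts[(A, B)] == {A: 2}
        assert store.counts[(B, A)] == {B: 1}

    def test_count_consistency(self):
        """Continuation totals of context c equal occurrences of c followed
        by anything."""
        store = NGramStore(max_order=3)
        seq = [A, B, A, C, B, A, B, C, A, A]
        store.add_sequence(seq, update_exclusion=False)
        for ctx, counter in store.counts.items():
            k = len(ctx)
            occurrences = sum(
                1 for i in range(len(seq) - k)
                if tuple(seq[i:i + k]) == ctx)
            assert sum(counter.values()) == occurrences

    def test_update_exclusion_stops_at_seen_symbol(self):
        store = NGramStore(max_order=1)
        store.add_sequence([A, B, A, B, A], update_exclusion=True)
        # second and third A's are already predicted by their bigram context
        # after the first occurrences, so order-0 counts stay smaller
        assert store.counts[()][A] < 3

    def test_train_ltm_empty_corpus_rejected(self):
        with pytest.raises((MelodyValidationError, TypeError)):
            train_ltm(Corpus(melodies=[]), ModelConfig())


def store_from(sequences, max_order=5, update_exclusion=False):
    store = NGramStore(max_order=max_order)
    for seq in sequences:
        store.add_sequence(seq, update_exclusion=update_exclusion)
    return store


class TestPPMAgainstOracle:
    """Exact equivalence with the rational-arithmetic escape recursion."""

    @pytest.mark.parametrize("escape", ["A", "C", "D"])
    @pytest.mark.parametrize("smoothing", ["interpolated", "backoff"])
    @pytest.mark.parametrize("order_bound", [0, 1, 2, VARIABLE])
    def test_exhaustive_small_corpora(self, escape, smoothing, order_bound):
        alphabet = [A, B, C]
        config = ModelConfig(order_bound=order_bound, escape_method=escape,
                             smoothing=smoothing, configuration=LTM)
        rng = np.random.default_rng(12)
        for trial in range(30):
            length = int(rng.integers(1, 11))
            seq = [alphabet[i] for i in rng.integers(0, 3, size=length)]
            store = store_from([seq], update_exclusion=bool(trial % 2))
            ctx_len = int(rng.integers(0, 4))
            context = tuple(alphabet[i]
                            for i in rng.integers(0, 3, size=ctx_len))
            expected = ppm_oracle(
                {c: dict(v) for c, v in store.counts.items()},
                context, alphabet, escape=escape, order_bound=order_bound,
                max_order=store.max_order, smoothing=smoothing)
            got = ppm_distribution(store, context, alphabet, config)
            for sym, p in zip(alphabet, got):
                assert abs(p - float(expected[sym])) < 1e-12

    def test_empty_store_is_uniform(self):
        store = NGramStore()
        config = ModelConfig(configuration=LTM)
        p = ppm_distribution(store, (), [A, B, C], config)
        assert np.allclose(p, 1 / 3)

    def test_seen_symbol_beats_unseen(self):
        store = store_from([[A, B]])
        config = ModelConfig(configuration=LTM)
        p_b = ppm_probability(store, (A,), B, [A, B, C], config)
        p_c = ppm_probability(store, (A,), C, [A, B, C], config)
        assert p_b > p_c > 0

    def test_hand_computed_escape_c(self):
        """P(b | a) for counts from (a,b,a,b,a), order 1, escape C.

        Exact value from the oracle's rational recursion, frozen here:
        context (a): counts {b: 2}, n=2, t=1 -> ml = 2/3, gamma = 1/3;
        order 0: counts {a:3, b:2}, n=5, t=2 -> p0(b) = 2/7 + (2/7)(1/3);
        P(b|a) = 2/3 + 1/3 * p0(b), all renormalized over {a,b,c}.
        """
        store = store_from([[A, B, A, B, A]], max_order=1)
        config = ModelConfig(order_bound=1, configuration=LTM)
        expected = ppm_oracle(
            {c: dict(v) for c, v in store.counts.items()}, (A,), [A, B, C],
            order_bound=1, max_order=1)
        got = ppm_probability(store, (A,), B, [A, B, C], config)
        assert got == pytest.approx(float(expected[B]), abs=1e-15)
        # the dominant continuation dominates
        assert float(expected[B]) > 0.6

    def test_probabilities_sum_to_one_and_positive(self):
        rng = np.random.default_rng(5)
        alphabet = [A, B, C]
        for _ in range(20):
            seq = [alphabet[i] for i in rng.integers(0, 3, size=8)]
            store = store_from([seq])
            for k in (0, 2):
                config = ModelConfig(order_bound=k, configuration=LTM)
                p = ppm_distribution(store, tuple(seq[:3]), alphabet, config)
                assert abs(p.sum() - 1.0) < 1e-9
                assert p.min() > 0


class TestCombineDistributions:
    def d(self, probs):
        return PredictiveDistribution(alphabet=tuple(range(len(probs))),
                                      p=np.asarray(probs, float))

    def test_identity(self):
        d1 = self.d([0.6, 0.3, 0.1])
        out = combine_distributions(d1, self.d([0.6, 0.3, 0.1]), b=1.0)
        assert np.allclose(out.p, d1.p, atol=1e-12)

    def test_uniform_partner_at_b0_is_sqrt(self):
        d2 = self.d([0.7, 0.2, 0.1])
        uniform = self.d([1 / 3] * 3)
        out = combine_distributions(uniform, d2, b=0.0)
        expected = np.sqrt(d2.p)
        expected /= expected.sum()
        assert np.allclose(out.p, expected, atol=1e-12)

    def test_bias_favors_confident_submodel(self):
        spiky = self.d([0.9799, 0.01, 0.0101])
        uniform = self.d([1 / 3] * 3)
        flat_combo = combine_distributions(spiky, uniform, b=0.0)
        biased = combine_distributions(spiky, uniform, b=2.0)
        tv_flat = 0.5 * np.abs(flat_combo.p - spiky.p).sum()
        tv_biased = 0.5 * np.abs(biased.p - spiky.p).sum()
        assert tv_biased < tv_flat

    def test_alphabet_mismatch_rejected(self):
        d1 = self.d([0.5, 0.5])
        d2 = PredictiveDistribution(alphabet=(9, 10), p=np.array([0.5, 0.5]))
        with pytest.raises(MelodyValidationError):
            combine_distributions(d1, d2)


class TestPredictNext:
    def test_dominant_continuation_wins(self, c_major):
        # 62 always follows 60 in training
        corpus = Corpus(melodies=[
            melody_from_pitches([60, 62, 64, 60, 62, 65, 60, 62],
                                mid=f"m{i}", key=c_major)
            for i in range(3)])
        config = ModelConfig(configuration=LTM)
        ltm = train_ltm(corpus, config)
        context = melody_from_pitches([64, 60], key=c_major)
        d = predict_next(ltm, None, context, c_major, corpus.alphabet, config)
        assert d.argmax_pitch() == 62

    def test_both_with_identical_stores_matches_single(self, c_major,
                                                       toy_corpus):
        config_l = ModelConfig(configuration=LTM)
        ltm = train_ltm(toy_corpus, config_l)
        context = melody_from_pitches([60, 62], key=c_major)
        alphabet = toy_corpus.alphabet
        single = predict_next(ltm, None, context, c_major, alphabet, config_l)
        both = predict_next(ltm, ltm, context, c_major, alphabet,
                            ModelConfig(configuration=BOTH))
        assert np.allclose(both.p, single.p, atol=1e-12)

    def test_order0_ignores_context(self, c_major, toy_corpus):
        config = ModelConfig(order_bound=0, configuration=LTM)
        ltm = train_ltm(toy_corpus, config)
        alphabet = toy_corpus.alphabet
        d1 = predict_next(ltm, None, melody_from_pitches([60, 62], key=c_major),
                          c_major, alphabet, config)
        d2 = predict_next(ltm, None, melody_from_pitches([67, 62], key=c_major),
                          c_major, alphabet, config)
        # same final pitch -> same candidate symbols -> identical distribution
        assert np.allclose(d1.p, d2.p, atol=1e-12)

    def test_empty_alphabet_rejected(self, c_major, toy_corpus):
        config = ModelConfig(configuration=LTM)
        ltm = train_ltm(toy_corpus, config)
        with pytest.raises(MelodyValidationError):
            predict_next(ltm, None, None, c_major, [], config)


class TestSequencePredictions:
    def test_output_length(self, c_major, toy_melody, toy_corpus):
        config = ModelConfig(configuration=LTM)
        ltm = train_ltm(toy_corpus, config)
        preds = sequence_predictions(toy_melody, ltm, c_major, config,
                                     toy_corpus.alphabet)
        assert len(preds) == len(toy_melody)
        for d in preds:
            assert abs(d.p.sum() - 1.0) < 1e-9
            assert d.p.min() > 0

    def test_stm_learns_repetition(self, c_major):
        """P(b | a) strictly grows with each (a, b) repetition under STM."""
        melody = melody_from_pitches([60, 62] * 6, key=c_major)
        config = ModelConfig(configuration=STM)
        preds = sequence_predictions(melody, None, c_major, config,
                                     (60, 62, 64))
        # predictions for the 'b' notes (odd positions, after first pair)
        p_b = [preds[i].probability(62) for i in range(3, len(melody), 2)]
        assert all(b > a for a, b in zip(p_b, p_b[1:]))

    def test_stm_near_uniform_on_novel_melody(self, c_major):
        melody = melody_from_pitches(list(range(60, 70)), key=c_major)
        config = ModelConfig(configuration=STM, update_exclusion=False)
        alphabet = tuple(range(58, 74))
        preds = sequence_predictions(melody, None, c_major, config, alphabet)
        # every transition is novel: escape dominates, so no pitch is ever
        # assigned a large share of the mass
        for d in preds[1:]:
            assert d.p.max() < 3.5 / len(alphabet)


class TestRecovery:
    """An order-1 model trained on a known chain recovers its statistics."""

    @staticmethod
    def chain_spec():
        alphabet = (60, 62, 64, 65)  # within one octave: degrees injective
        rows = np.array([
            [0.70, 0.10, 0.10, 0.10],
            [0.10, 0.70, 0.10, 0.10],
            [0.10, 0.10, 0.70, 0.10],
            [0.10, 0.10, 0.10, 0.70],
        ])
        return GrammarSpec(alphabet=alphabet,
                           transition=tuple(map(tuple, rows)),
                           initial=(0.25,) * 4, phrase_length=(50, 50),
                           key=Key(0, "major"))

    def fit_and_eval(self, n_events, seed=77):
        spec = self.chain_spec()
        notes = 50
        corpus = generate_markov_corpus(spec, max(n_events // notes, 1),
                                        notes, seed=seed)
        config = ModelConfig(order_bound=1, configuration=LTM)
        ltm = train_ltm(corpus, config)
        held_out = generate_markov_corpus(spec, 1, 400, seed=seed + 1)
        melody = held_out.melodies[0]
        preds = sequence_predictions(melody, ltm, Key(0, "major"), config,
                                     spec.alphabet)
        T = spec.matrix
        idx = {p: i for i, p in enumerate(spec.alphabet)}
        kls, entropies = [], []
        for i in range(2, len(melody)):
            row = T[idx[melody.pitches[i - 1]]]
            q = preds[i].p
            kls.append(float(np.sum(row * np.log2(row / q))))
            entropies.append(entropy(preds[i]))
        return float(np.mean(kls)), float(np.mean(entropies))

    def test_kl_decreases_with_training_size(self):
        kl_100, _ = self.fit_and_eval(100)
        kl_1k, _ = self.fit_and_eval(1_000)
        kl_10k, _ = self.fit_and_eval(10_000)
        assert kl_100 > kl_1k > kl_10k

    def test_entropy_matches_analytic_value(self):
        spec = self.chain_spec()
        target = analytic_chain_entropy(spec)
        _, mean_h = self.fit_and_eval(10_000)
        assert abs(mean_h - target) < 0.05


class TestVariableOrderAdvantage:
    def test_log_probability_non_decreasing_to_best_order(self):
        """Held-out per-note log-probability improves with order up to the
        best fixed order, and variable order is at least as good as order 0."""
        alphabet = (60, 62, 64, 65, 67)
        rng = np.random.default_rng(3)
        rows = rng.dirichlet(np.full(5, 0.4), size=5)
        spec = GrammarSpec(alphabet=alphabet,
                           transition=tuple(map(tuple, rows)),
                           initial=(0.2,) * 5, phrase_length=(40, 40),
                           key=Key(0, "major"))
        train = generate_markov_corpus(spec, 50, 40, seed=10)
        held = generate_markov_corpus(spec, 5, 40, seed=11)

        def mean_lp(order):
            config = ModelConfig(order_bound=order, configuration=LTM)
            ltm = train_ltm(train, config)
            lps = []
            for melody in held.melodies:
                preds = sequence_predictions(melody, ltm, Key(0, "major"),
                                             config, alphabet)
                lps.extend(math.log2(d.probability(p))
                           for d, p in zip(preds[1:], melody.pitches[1:]))
            return float(np.mean(lps))

        fixed = [mean_lp(k) for k in range(4)]
        best = int(np.argmax(fixed))
        assert all(fixed[i] <= fixed[i + 1] + 1e-12 for i in range(best))

    def test_variable_order_excels_on_deep_structure(self):
        """Where long contexts are genuinely predictive (a repeated motif),
        the variable-order strategy beats low fixed orders."""
        rng = np.random.default_rng(8)
        motif = [int(p) for p in rng.choice((60, 62, 64, 65, 67), size=12)]
        alphabet = tuple(sorted(set(motif)))
        corpus = Corpus(melodies=[
            melody_from_pitches(motif * 4, mid=f"m{i}", key=Key(0, "major"))
            for i in range(10)])
        held = melody_from_pitches(motif * 4, mid="held", key=Key(0, "major"))

        def mean_lp(order):
            config = ModelConfig(order_bound=order, configuration=LTM)
            ltm = train_ltm(corpus, config)
            preds = sequence_predictions(held, ltm, Key(0, "major"), config,
                                         alphabet)
            return float(np.mean([math.log2(d.probability(p))
                                  for d, p in zip(preds[1:],
                                                  held.pitches[1:])]))

        lp0, lp1, lp_var = mean_lp(0), mean_lp(1), mean_lp(VARIABLE)
        assert lp_var > lp1 > lp0


def test_store_json_round_trip(toy_corpus, tmp_path):
    config = ModelConfig(configuration=LTM)
    ltm = train_ltm(toy_corpus, config)
    path = tmp_path / "model.json"
    ltm.save(path)
    back = NGramStore.load(path)
    assert back.counts == ltm.counts
    assert back.max_order == ltm.max_order


def test_build_alphabet_policies(toy_corpus):
    assert build_alphabet(toy_corpus, "corpus") == toy_corpus.alphabet
    span = build_alphabet(toy_corpus, "chromatic_span")
    assert span == tuple(range(min(toy_corpus.alphabet),
                               max(toy_corpus.alphabet) + 1))
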