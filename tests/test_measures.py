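"""Cohort probabilities, entropy, next-segment prediction, prediction error.

The brute-force oracle used here recomputes every quantity by scanning the
word list directly and accumulating raw frequencies, independently of the
library's cohort machinery.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexicohort import (
    cohort,
    lexical_entropy,
    next_segment_distribution,
    segment_prediction_error,
    timecourse,
)
from lexicohort.lexicon import LexiconError, parse_transcription

from conftest import make_lexicon, random_lexicon

PREFIX = tuple("k@ptI")

# Independently hand-computed: p = (71/79, 8/79),
# H = -(p1*log2(p1) + p2*log2(p2)) = 0.47299536229314815 bits.
CAPTAIN_ENTROPY = 0.47299536229314815


def brute_force_cohort(words, prefix):
    """Oracle: direct scan accumulating frequencies of prefix matches."""
    matches = [(t, f) for t, f in words if t[: len(prefix)] == tuple(prefix)]
    total = sum(f for _, f in matches)
    if not matches:
        return {}
    if total == 0:
        return {t: 1 / len(matches) for t, _ in matches}
    return {t: f / total for t, f in matches}


def brute_force_next_segment(words, prefix):
    """Oracle: accumulate raw frequency mass per continuation segment."""
    probs = brute_force_cohort(words, prefix)
    dist = {}
    for t, p in probs.items():
        if len(t) > len(prefix):
            dist[t[len(prefix)]] = dist.get(t[len(prefix)], 0.0) + p
    return dist


class TestCohort:
    def test_worked_example_probabilities(self, captain_captive):
        c = cohort(captain_captive, PREFIX)
        probs = {e.orthography: p for e, p in c.members}
        assert round(probs["captain"], 3) == 0.899
        assert round(probs["captive"], 3) == 0.101

    def test_single_match_has_probability_one(self, captain_captive):
        c = cohort(captain_captive, tuple("k@ptIn"))
        assert len(c) == 1
        assert c.members[0][1] == pytest.approx(1.0)

    def test_no_match_gives_empty_cohort(self, captain_captive):
        assert len(cohort(captain_captive, tuple("zzz"))) == 0

    def test_zero_frequency_cohort_is_uniform(self):
        lex = make_lexicon(("cat", "cat", 0.0), ("cab", "cab", 0.0))
        c = cohort(lex, tuple("ca"))
        assert [p for _, p in c.members] == pytest.approx([0.5, 0.5])


class TestLexicalEntropy:
    def test_singleton_is_zero(self, captain_captive):
        assert lexical_entropy(cohort(captain_captive, tuple("k@ptIn"))) == 0.0

    def test_empty_is_zero(self, captain_captive):
        assert lexical_entropy(cohort(captain_captive, tuple("zzz"))) == 0.0

    def test_uniform_pair_is_one_bit(self):
        lex = make_lexicon(("cat", "cat", 5.0), ("cab", "cab", 5.0))
        assert lexical_entropy(cohort(lex, tuple("ca"))) == pytest.approx(1.0)

    def test_worked_example_value(self, captain_captive):
        h = lexical_entropy(cohort(captain_captive, PREFIX))
        assert h == pytest.approx(CAPTAIN_ENTROPY, abs=1e-12)


class TestNextSegmentDistribution:
    def test_worked_example_distribution(self, captain_captive):
        d = next_segment_distribution(captain_captive, PREFIX)
        assert set(d) == {"n", "v"}
        assert round(d["n"], 3) == 0.899
        assert round(d["v"], 3) == 0.101

    def test_shared_next_segment_gets_all_mass(self, captain_captive):
        d = next_segment_distribution(captain_captive, tuple("k@p"))
        assert d == pytest.approx({"t": 1.0})

    def test_three_equal_words_uniform(self):
        lex = make_lexicon(("cat", "cat", 7.0), ("cob", "cob", 7.0), ("cup", "cup", 7.0))
        d = next_segment_distribution(lex, tuple("c"))
        assert d == pytest.approx({"a": 1 / 3, "o": 1 / 3, "u": 1 / 3})

    def test_end_marker_is_predictable(self):
        lex = make_lexicon(("cat", "cat", 6.0), ("cats", "cats", 2.0))
        d = next_segment_distribution(lex, tuple("cat"))
        assert d == pytest.approx({"#": 0.75, "s": 0.25})

    def test_empty_cohort_gives_empty_distribution(self, captain_captive):
        assert next_segment_distribution(captain_captive, tuple("zzz")) == {}


class TestSegmentPredictionError:
    def test_printed_worked_example(self):
        # Evaluated on the probabilities at printed 3-d.p. precision,
        # as in the worked arithmetic: |1-0.899| + |0-0.101| = 0.202.
        assert segment_prediction_error(
            {"n": 0.899, "v": 0.101}, "n"
        ) == pytest.approx(0.202, abs=1e-12)

    def test_full_precision_worked_example(self, captain_captive):
        d = next_segment_distribution(captain_captive, PREFIX)
        assert segment_prediction_error(d, "n") == pytest.approx(
            16 / 79, abs=1e-12
        )

    def test_perfect_prediction_is_zero(self):
        assert segment_prediction_error({"s": 1.0}, "s") == 0.0

    def test_fully_wrong_prediction_is_two(self):
        assert segment_prediction_error({"l": 0.5, "b": 0.5}, "t") == pytest.approx(2.0)

    def test_empty_prediction_is_one(self):
        assert segment_prediction_error({}, "s") == 1.0

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0),
            min_size=1,
            max_size=8,
        ),
        st.integers(min_value=0, max_value=8),
    )
    @settings(derandomize=True, max_examples=200)
    def test_closed_form_two_times_miss(self, weights, heard_idx):
        """Eq.-4-style summed error equals 2*(1 - mass on heard segment)."""
        total = sum(weights)
        segs = [f"s{i}" for i in range(len(weights))]
        d = {s: w / total for s, w in zip(segs, weights)}
        heard = segs[heard_idx % len(segs)]
        assert segment_prediction_error(d, heard) == pytest.approx(
            2 * (1 - d[heard]), abs=1e-12
        )


class TestTimecourse:
    def test_worked_example_timecourse(self, captain_captive):
        tc = timecourse(captain_captive, parse_transcription("k@ptIn"))
        # /n/ is position 6; before it the two words are indistinguishable
        assert tc.prediction_error[5] == pytest.approx(16 / 79, abs=1e-12)
        assert tc.entropy[5] == 0.0  # only captain matches /k@ptIn/
        assert tc.entropy[4] == pytest.approx(CAPTAIN_ENTROPY, abs=1e-12)
        assert tc.cohort_size == (2, 2, 2, 2, 2, 1, 1)

    def test_sole_word_predicts_perfectly(self, formula_toy):
        tc = timecourse(formula_toy, parse_transcription("formula"))
        assert tc.prediction_error == pytest.approx((0.0,) * 8)
        assert tc.entropy == pytest.approx((0.0,) * 8)

    def test_divergence_then_dead_cohort(self):
        # Hand-evaluated on {cat, cow, dog}, stimulus "cz#": position 1
        # error = 2*(1 - 2/3); position 2 prediction {a,o} misses z -> 2;
        # position 3 cohort empty -> 1.
        lex = make_lexicon(("cat", "cat", 1.0), ("cow", "cow", 1.0), ("dog", "dog", 1.0))
        tc = timecourse(lex, parse_transcription("cz"))
        assert tc.prediction_error == pytest.approx((2 / 3, 2.0, 1.0), abs=1e-12)
        assert tc.cohort_size == (2, 0, 0)
        assert tc.entropy[1:] == pytest.approx((0.0, 0.0))

    def test_missing_end_marker_rejected(self, captain_captive):
        with pytest.raises(LexiconError):
            timecourse(captain_captive, tuple("k@ptIn"))


class TestPropertiesOnRandomLexicons:
    def test_normalization_and_ranges(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            lex = random_lexicon(rng, int(rng.integers(1, 30)))
            length = int(rng.integers(0, 4))
            prefix = tuple(
                "abc"[i] for i in rng.integers(0, 3, length)
            )
            c = cohort(lex, prefix)
            if len(c):
                assert sum(p for _, p in c.members) == pytest.approx(1.0, abs=1e-12)
                h = lexical_entropy(c)
                assert 0.0 <= h <= math.log2(len(c)) + 1e-12
            d = next_segment_distribution(lex, prefix)
            if d:
                assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)
                assert all(0.0 <= p <= 1.0 for p in d.values())

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            lex = random_lexicon(rng, int(rng.integers(1, 51)))
            words = [(e.transcription, e.frequency) for e in lex]
            length = int(rng.integers(0, 4))
            prefix = tuple("abc"[i] for i in rng.integers(0, 3, length))
            expected = brute_force_cohort(words, prefix)
            got = {e.transcription: p for e, p in cohort(lex, prefix).members}
            assert set(got) == set(expected)
            for k in expected:
                assert got[k] == pytest.approx(expected[k], abs=1e-12)
            exp_dist = brute_force_next_segment(words, prefix)
            got_dist = next_segment_distribution(lex, prefix)
            assert set(got_dist) == set(exp_dist)
            for k in exp_dist:
                assert got_dist[k] == pytest.approx(exp_dist[k], abs=1e-12)

    def test_cohort_shrinks_monotonically(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            lex = random_lexicon(rng, 20)
            prefix = tuple("abc"[i] for i in rng.integers(0, 3, 2))
            base = {e.transcription for e in cohort(lex, prefix).entries}
            for seg in "abc#":
                extended = {
                    e.transcription
                    for e in cohort(lex, prefix + (seg,)).entries
                }
                assert extended <= base
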