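"""Shared fixtures: tiny hand-checkable lexicons and random generators."""

from __future__ import annotations

import numpy as np
import pytest

from lexicohort import LexicalEntry, Lexicon, merge_homophones
from lexicohort.lexicon import parse_transcription


def make_lexicon(*rows: tuple[str, str, float]) -> Lexicon:
    """Build a lexicon from (orthography, transcription, frequency) rows."""
    return merge_homophones(
        LexicalEntry(orth, parse_transcription(trans), freq)
        for orth, trans, freq in rows
    )


@pytest.fixture
def captain_captive() -> Lexicon:
    """The two-word frequency-weighted cohort of the worked example."""
    return make_lexicon(("captain", "k@ptIn", 71.0), ("captive", "k@ptIv", 8.0))


@pytest.fixture
def formula_toy() -> Lexicon:
    """One-word base lexicon for the equal-frequency learning toy."""
    return make_lexicon(("formula", "formula", 10.0))


def random_lexicon(
    rng: np.random.Generator,
    n_words: int,
    alphabet: str = "abc",
    max_len: int = 4,
) -> Lexicon:
    """Small random lexicon for property and oracle tests."""
    entries = []
    seen = set()
    while len(entries) < n_words:
        length = int(rng.integers(1, max_len + 1))
        word = "".join(
            alphabet[i] for i in rng.integers(0, len(alphabet), length)
        )
        trans = parse_transcription(word)
        if trans in seen:
            continue
        seen.add(trans)
        freq = float(rng.uniform(0.1, 100.0))
        entries.append(LexicalEntry(f"w{len(entries)}", trans, freq))
    return merge_homophones(entries)
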