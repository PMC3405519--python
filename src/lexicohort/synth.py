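"""Synthetic lexicons and word-learning triplets.

Stands in for a licensed pronunciation database: random segment-string
words with Zipfian rank-frequency structure, and source/novel/baseline
triplets that share a prefix up to a deviation point at which all three
diverge, with the source word's uniqueness point strictly earlier.

Frequencies follow a rank-frequency power law scaled to occurrences per
million: f(r) = 1e6 * r^(-s) / H_n(s), so the rank-1 : rank-10 ratio is
exactly 10^s.  No phonotactic realism is attempted (any segment can follow
any other); the generator controls only word length, inventory size and
deviation-point placement.

All sampling flows through one numpy Generator seeded from the config, so
generation is a pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from lexicohort.lexicon import (
    END_MARKER,
    LexicalEntry,
    Lexicon,
    Segment,
)
from lexicohort.experiment import Triplet, uniqueness_point

#: Fixed alphabet the segment inventory is drawn from (never the end marker).
ALPHABET = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


class GenerationError(RuntimeError):
    """Raised when the sampler cannot satisfy the design constraints."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic lexicon/triplet generator.

    Defaults emulate the scale of a monomorphemic-word recognition
    experiment: a vocabulary of a thousand content words of 4-8 segments
    over a 20-symbol inventory, a classical Zipf exponent of 1, and 50
    triplets whose deviation point falls 1-3 segments before word offset
    (as in *formula*/*formubo*, which diverge at the penultimate vowel).
    """

    inventory_size: int = 20
    n_words: int = 1000
    word_length_range: tuple[int, int] = (4, 8)
    zipf_exponent: float = 1.0
    n_triplets: int = 50
    dp_offset_range: tuple[int, int] = (1, 3)
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.inventory_size < 3:
            raise ValueError(
                "inventory_size must be >= 3 (the three triplet forms need "
                "distinct segments at the deviation point)"
            )
        if self.inventory_size > len(ALPHABET):
            raise ValueError(
                f"inventory_size must be <= {len(ALPHABET)}"
            )
        lo, hi = self.word_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad word_length_range: {self.word_length_range}")
        lo, hi = self.dp_offset_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad dp_offset_range: {self.dp_offset_range}")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")

    @property
    def inventory(self) -> tuple[Segment, ...]:
        return tuple(ALPHABET[: self.inventory_size])


def zipf_frequencies(n: int, exponent: float) -> np.ndarray:
    """Per-million frequencies for ranks 1..n under a rank power law."""
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks ** (-exponent)
    return 1e6 * weights / weights.sum()


def generate_lexicon(config: SynthConfig) -> Lexicon:
    """Sample ``config.n_words`` distinct random words with Zipfian frequencies.

    Word lengths are uniform over ``word_length_range`` and segments uniform
    over the inventory; rank order (and hence frequency) follows generation
    order.  Deterministic given ``config.seed``.

    Raises
    ------
    GenerationError
        If distinct transcriptions cannot be found (inventory too small
        for ``n_words``).
    """
    rng = np.random.default_rng(config.seed)
    inventory = config.inventory
    lo, hi = config.word_length_range
    seen: set[tuple[Segment, ...]] = set()
    words: list[tuple[Segment, ...]] = []
    attempts = 0
    while len(words) < config.n_words:
        if attempts > config.max_attempts * max(config.n_words, 1):
            raise GenerationError(
                f"could not sample {config.n_words} distinct words of length "
                f"{lo}-{hi} over {len(inventory)} segments"
            )
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        word = tuple(
            inventory[i] for i in rng.integers(0, len(inventory), length)
        )
        transcription = word + (END_MARKER,)
        if transcription in seen:
            continue
        seen.add(transcription)
        words.append(transcription)
    frequencies = zipf_frequencies(len(words), config.zipf_exponent)
    entries = [
        LexicalEntry(
            orthography=f"w{rank:05d}",
            transcription=transcription,
            frequency=float(freq),
        )
        for rank, (transcription, freq) in enumerate(
            zip(words, frequencies), start=1
        )
    ]
    return Lexicon(entries={e.transcription: e for e in entries})


def _divergent_segments(
    lexicon: Lexicon,
    prefix: Sequence[Segment],
    inventory: Sequence[Segment],
    exclude: Segment,
    rng: np.random.Generator,
) -> tuple[Segment, Segment] | None:
    """Two distinct segments at ``len(prefix)+1`` used by no cohort member.

    Substituting either one guarantees the resulting form diverges from
    every lexicon entry at the deviation point, hence is a nonword.
    """
    at = len(prefix)
    used = {
        e.transcription[at]
        for e in lexicon.prefix_matches(prefix)
        if len(e.transcription) > at
    }
    used.add(exclude)
    free = [s for s in inventory if s not in used]
    if len(free) < 2:
        return None
    picks = rng.choice(len(free), size=2, replace=False)
    return free[picks[0]], free[picks[1]]


def generate_triplets(
    lexicon: Lexicon, config: SynthConfig
) -> list[Triplet]:
    """Sample validated source/novel/baseline triplets from a lexicon.

    For each triplet: a source word is drawn (without replacement), a
    deviation point is placed ``dp_offset_range`` segments before its end
    marker and after its uniqueness point, and the novel and baseline
    forms are built by substituting distinct unused segments at the DP and
    completing the tail with uniform random segments.  Divergence at the
    DP from every cohort member guarantees both forms are nonwords.

    Raises
    ------
    GenerationError
        If too few source words satisfy the UP < DP constraint, naming the
        constraint that failed.
    """
    rng = np.random.default_rng(config.seed + 1)  # distinct from lexicon stream
    inventory = config.inventory
    entries = list(lexicon)
    order = rng.permutation(len(entries))
    triplets: list[Triplet] = []
    failures = {"up_before_dp": 0, "dp_segments": 0}
    for idx in order:
        if len(triplets) >= config.n_triplets:
            break
        source = entries[idx]
        n_pos = len(source.transcription)  # includes end marker
        up = uniqueness_point(lexicon, source.transcription)
        lo, hi = config.dp_offset_range
        candidates = [
            n_pos - off
            for off in range(lo, hi + 1)
            if 2 <= n_pos - off <= n_pos - 1 and up < n_pos - off
        ]
        if not candidates:
            failures["up_before_dp"] += 1
            continue
        dp = int(rng.choice(candidates))
        prefix = source.transcription[: dp - 1]
        picks = _divergent_segments(
            lexicon, prefix, inventory, source.transcription[dp - 1], rng
        )
        if picks is None:
            failures["dp_segments"] += 1
            continue
        novel_seg, baseline_seg = picks
        tail_len = n_pos - 1 - dp  # real segments after the DP
        novel_tail = tuple(
            inventory[i] for i in rng.integers(0, len(inventory), tail_len)
        )
        baseline_tail = tuple(
            inventory[i] for i in rng.integers(0, len(inventory), tail_len)
        )
        novel = prefix + (novel_seg,) + novel_tail + (END_MARKER,)
        baseline = prefix + (baseline_seg,) + baseline_tail + (END_MARKER,)
        triplet = Triplet(
            source=source,
            novel=novel,
            baseline=baseline,
            dp_index=dp,
            up_index=up,
        )
        triplet.validate(lexicon)
        triplets.append(triplet)
    if len(triplets) < config.n_triplets:
        raise GenerationError(
            f"only {len(triplets)}/{config.n_triplets} triplets satisfiable; "
            f"rejections: no DP position with UP < DP for "
            f"{failures['up_before_dp']} words, too few free DP segments for "
            f"{failures['dp_segments']} words"
        )
    return triplets
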