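"""Ideal-observer cohort measures over an incremental speech signal.

Given error-free segment recognizers, the cohort after hearing a prefix is
the set of words whose transcription begins with it; each word's conditional
probability is its frequency divided by the summed frequency of the cohort:

    p(word_i | speech) = f(word_i) / sum_j f(word_j)          (cohort)

Two measures summarize the cohort at each segment position:

* lexical entropy, the Shannon entropy (bits) of the word distribution —
  the uncertainty a lexical-competition account must resolve;
* segment prediction error, the summed absolute difference between the
  predicted next-segment distribution and the observed 1/0 pattern — the
  residual a segment-prediction account must transmit.

For a normalized prediction d and heard segment s the prediction error is
algebraically 2 * (1 - d[s]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from lexicohort.lexicon import (
    END_MARKER,
    LexicalEntry,
    Lexicon,
    LexiconError,
    Segment,
    Transcription,
)

#: Prediction error charged per segment once the cohort is empty: the heard
#: segment contributes |1 - 0| against an empty prediction.
EMPTY_COHORT_ERROR = 1.0

SegmentDistribution = dict[Segment, float]


@dataclass(frozen=True)
class Cohort:
    """Words compatible with a heard prefix, with conditional probabilities."""

    prefix: Transcription
    members: tuple[tuple[LexicalEntry, float], ...]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def entries(self) -> tuple[LexicalEntry, ...]:
        return tuple(e for e, _ in self.members)

    def probability_of(self, entry: LexicalEntry) -> float:
        for member, p in self.members:
            if member.transcription == entry.transcription:
                return p
        return 0.0


def cohort(lexicon: Lexicon, prefix: Sequence[Segment]) -> Cohort:
    """Frequency-normalized cohort of words matching ``prefix``.

    An empty cohort is a valid return (the prefix matches no word).  If all
    matching words have zero frequency the distribution over them is
    uniform, so that zero-frequency entries stay representable.
    """
    prefix = tuple(prefix)
    matches = lexicon.prefix_matches(prefix)
    total = sum(e.frequency for e in matches)
    if not matches:
        return Cohort(prefix=prefix, members=())
    if total > 0:
        members = tuple((e, e.frequency / total) for e in matches)
    else:
        members = tuple((e, 1.0 / len(matches)) for e in matches)
    return Cohort(prefix=prefix, members=members)


def lexical_entropy(cohort: Cohort) -> float:
    """Shannon entropy (bits) of the cohort's word distribution.

    Zero for an empty or singleton cohort; ``0 * log 0`` is treated as 0.
    """
    h = 0.0
    for _, p in cohort.members:
        if p > 0.0:
            h -= p * math.log2(p)
    return h


def next_segment_distribution(
    lexicon: Lexicon, prefix: Sequence[Segment]
) -> SegmentDistribution:
    """Conditional distribution over the segment following ``prefix``.

    Each cohort member votes its conditional probability for the segment it
    continues with; the end-of-word marker is a possible next segment.
    Returns an empty mapping for an empty cohort.
    """
    prefix = tuple(prefix)
    c = cohort(lexicon, prefix)
    dist: SegmentDistribution = {}
    at = len(prefix)
    for entry, p in c.members:
        if len(entry.transcription) > at:
            seg = entry.transcription[at]
            dist[seg] = dist.get(seg, 0.0) + p
    return dist


def segment_prediction_error(
    prediction: Mapping[Segment, float], heard: Segment
) -> float:
    """Summed absolute error between predicted and observed segment probabilities.

    The observed probability is 1 for the heard segment and 0 for every
    other predicted segment.  For an empty prediction the heard segment
    alone contributes ``|1 - 0| = 1``.
    """
    error = abs(1.0 - prediction.get(heard, 0.0))
    for seg, p in prediction.items():
        if seg != heard:
            error += abs(p)
    return error


@dataclass(frozen=True)
class MeasureTimecourse:
    """Per-position cohort measures for one stimulus.

    All arrays are indexed by segment position ``t`` (0-based internally;
    positions are conventionally reported 1-based).  ``prediction[t]`` is
    the next-segment distribution formed *before* hearing segment ``t``;
    ``cohort_size[t]`` and ``entropy[t]`` describe the state *after*
    hearing segment ``t``.
    """

    stimulus: Transcription
    cohort_size: tuple[int, ...]
    entropy: tuple[float, ...]
    prediction: tuple[SegmentDistribution, ...]
    prediction_error: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.stimulus)


def timecourse(lexicon: Lexicon, stimulus: Sequence[Segment]) -> MeasureTimecourse:
    """Evaluate all cohort measures across a stimulus, segment by segment.

    ``stimulus`` must end with the end-of-word marker.  Once the cohort is
    empty it stays empty: every later prediction is empty and every later
    segment incurs a prediction error of 1.
    """
    stimulus = tuple(stimulus)
    if not stimulus or stimulus[-1] != END_MARKER:
        raise LexiconError(
            f"stimulus must end with {END_MARKER!r}: {stimulus!r}"
        )
    sizes: list[int] = []
    entropies: list[float] = []
    predictions: list[SegmentDistribution] = []
    errors: list[float] = []
    dead = False  # cohort has emptied at an earlier prefix
    for t in range(len(stimulus)):
        if dead:
            prediction: SegmentDistribution = {}
        else:
            prediction = next_segment_distribution(lexicon, stimulus[:t])
        predictions.append(prediction)
        if prediction:
            errors.append(segment_prediction_error(prediction, stimulus[t]))
        else:
            errors.append(EMPTY_COHORT_ERROR)
        c = cohort(lexicon, stimulus[: t + 1]) if not dead else None
        if c is None or len(c) == 0:
            dead = True
            sizes.append(0)
            entropies.append(0.0)
        else:
            sizes.append(len(c))
            entropies.append(lexical_entropy(c))
    return MeasureTimecourse(
        stimulus=stimulus,
        cohort_size=tuple(sizes),
        entropy=tuple(entropies),
        prediction=tuple(predictions),
        prediction_error=tuple(errors),
    )
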