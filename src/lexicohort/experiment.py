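"""Two-day word-learning experiment simulation.

The design crosses item type (source word, trained novel word, baseline
nonword — e.g. *formula*, *formubo*, *formuty*) with training day.  Novel
words trained on day 1 are assumed consolidated overnight and therefore
lexicalized: the day-1 lexicon contains them, at their source word's
frequency.  Day-2 items were trained but not consolidated, so the day-2
lexicon is the unmodified base lexicon.

Two landmarks index each triplet:

* uniqueness point (UP) — first position at which the source word is the
  only cohort member in the base lexicon;
* deviation point (DP) — first position at which the three forms diverge.

The design requires UP < DP: the source word is already unique when the
novel form splits off.  Measures are averaged within three windows defined
in segment positions — pre-DP (1..DP-1), post-DP (DP..offset, including
the end-of-word marker by default), and UP-locked (UP..DP-1) — first within
a stimulus, then across triplets, mirroring per-item epoching followed by
grand-averaging.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from lexicohort.lexicon import (
    DelimiterMode,
    LexicalEntry,
    Lexicon,
    LexiconError,
    Segment,
    Transcription,
    add_novel_word,
    format_transcription,
    parse_transcription,
)
from lexicohort.measures import MeasureTimecourse, cohort, timecourse

ITEM_TYPES = ("source", "novel", "baseline")
DAYS = ("day1", "day2")
WINDOWS = ("preDP", "postDP", "UPlocked")


class DesignError(ValueError):
    """Raised when a triplet or condition set violates the design."""


def uniqueness_point(lexicon: Lexicon, word: Sequence[Segment]) -> int:
    """1-based position at which ``word`` becomes the sole cohort member.

    If the word is a proper prefix of another lexicon entry, this is the
    end-marker position: the offset itself disambiguates.

    Raises
    ------
    LexiconError
        If ``word`` is not an entry of ``lexicon``.
    """
    word = tuple(word)
    if word not in lexicon:
        raise LexiconError(f"word not in lexicon: {word!r}")
    for t in range(1, len(word) + 1):
        members = cohort(lexicon, word[:t]).entries
        if all(e.transcription == word for e in members):
            return t
    # unreachable: the full transcription (with end marker) is unique
    raise AssertionError("no uniqueness point found")  # pragma: no cover


def deviation_point(triplet: "Triplet") -> int:
    """1-based position at which source, novel and baseline first diverge."""
    forms = (triplet.source.transcription, triplet.novel, triplet.baseline)
    for t in range(min(len(f) for f in forms)):
        if len({f[t] for f in forms}) > 1:
            return t + 1
    raise DesignError("triplet forms never diverge")


@dataclass(frozen=True)
class Triplet:
    """A source word with its trained novel form and untrained baseline.

    The three transcriptions share positions ``1..dp_index-1`` and are
    pairwise distinct at ``dp_index``; ``up_index`` is the source word's
    uniqueness point in the base (day-2) lexicon and must precede the DP.
    """

    source: LexicalEntry
    novel: Transcription
    baseline: Transcription
    dp_index: int
    up_index: int

    def validate(self, base: Lexicon | None = None) -> None:
        """Check all design invariants, raising :class:`DesignError`."""
        dp = self.dp_index
        forms = (self.source.transcription, self.novel, self.baseline)
        if deviation_point(self) != dp:
            raise DesignError(
                f"stored dp_index {dp} != computed {deviation_point(self)}"
            )
        if len({f[dp - 1] for f in forms}) != 3:
            raise DesignError(
                f"forms not pairwise distinct at DP position {dp}"
            )
        if not self.up_index < dp:
            raise DesignError(
                f"uniqueness point {self.up_index} must precede DP {dp}"
            )
        if base is not None:
            if self.source.transcription not in base:
                raise DesignError("source word missing from base lexicon")
            if self.novel in base or self.baseline in base:
                raise DesignError("novel/baseline form already in lexicon")
            up = uniqueness_point(base, self.source.transcription)
            if up != self.up_index:
                raise DesignError(
                    f"stored up_index {self.up_index} != computed {up}"
                )


def make_triplet(
    base: Lexicon,
    source: LexicalEntry,
    novel: Sequence[Segment],
    baseline: Sequence[Segment],
) -> Triplet:
    """Build a validated triplet, computing UP and DP from the base lexicon."""
    partial = Triplet(
        source=source,
        novel=tuple(novel),
        baseline=tuple(baseline),
        dp_index=0,
        up_index=0,
    )
    dp = deviation_point(partial)
    up = uniqueness_point(base, source.transcription)
    triplet = Triplet(
        source=source,
        novel=tuple(novel),
        baseline=tuple(baseline),
        dp_index=dp,
        up_index=up,
    )
    triplet.validate(base)
    return triplet


def read_triplets(
    path: str | Path,
    base: Lexicon,
    delimiter_mode: DelimiterMode = "single-char",
) -> list[Triplet]:
    """Read triplets from TSV and validate them against the base lexicon.

    Columns: source_orthography, source_transcription, novel_transcription,
    baseline_transcription.  UP and DP are computed, not read.  Lines
    starting with ``#`` and blank lines are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"triplet file not found: {path}")
    triplets: list[Triplet] = []
    problems: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                problems.append(f"line {lineno}: expected 4 columns")
                continue
            try:
                source_trans = parse_transcription(fields[1], delimiter_mode)
                novel = parse_transcription(fields[2], delimiter_mode)
                baseline = parse_transcription(fields[3], delimiter_mode)
                if source_trans not in base:
                    raise DesignError(
                        f"source {fields[0]!r} not in lexicon"
                    )
                triplets.append(
                    make_triplet(
                        base, base.entries[source_trans], novel, baseline
                    )
                )
            except (LexiconError, DesignError) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        raise DesignError(
            f"{path}: {len(problems)} invalid triplet row(s):\n  "
            + "\n  ".join(problems)
        )
    return triplets


def write_triplets(
    triplets: Iterable[Triplet],
    path: str | Path,
    delimiter_mode: DelimiterMode = "single-char",
) -> None:
    """Write triplets in the TSV dialect :func:`read_triplets` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(
            "# source_orthography\tsource_transcription\t"
            "novel_transcription\tbaseline_transcription\n"
        )
        for t in triplets:
            fh.write(
                "\t".join(
                    (
                        t.source.orthography,
                        format_transcription(t.source.transcription, delimiter_mode),
                        format_transcription(t.novel, delimiter_mode),
                        format_transcription(t.baseline, delimiter_mode),
                    )
                )
                + "\n"
            )


def build_day_lexicons(
    base: Lexicon,
    day1_triplets: Iterable[Triplet],
    day2_triplets: Iterable[Triplet] = (),
) -> tuple[Lexicon, Lexicon]:
    """Lexicons in force on each test day.

    The day-1 lexicon contains every day-1 trained novel word (consolidated
    overnight, hence lexicalized) at its source word's frequency; the day-2
    lexicon is the base unchanged (day-2 items trained but unconsolidated).

    Raises
    ------
    DesignError
        If a triplet appears in both assignments.
    """
    day1 = list(day1_triplets)
    day2 = list(day2_triplets)
    day1_novels = {t.novel for t in day1}
    if day1_novels & {t.novel for t in day2}:
        raise DesignError("a triplet is assigned to both training days")
    day1_lexicon = base
    for t in day1:
        day1_lexicon = add_novel_word(day1_lexicon, t.novel, t.source)
    return day1_lexicon, base


@dataclass(frozen=True)
class ConditionProfile:
    """Mean measures for one condition x analysis window."""

    item_type: str  # source | novel | baseline
    day: str  # day1 | day2
    window: str  # preDP | postDP | UPlocked
    mean_entropy: float
    mean_prediction_error: float
    n_triplets: int


def _window_positions(
    window: str, dp: int, up: int, length: int, include_offset: bool
) -> range:
    """0-based position range for a named analysis window."""
    last = length if include_offset else length - 1
    if window == "preDP":
        return range(0, dp - 1)
    if window == "postDP":
        return range(dp - 1, last)
    if window == "UPlocked":
        return range(up - 1, dp - 1)
    raise DesignError(f"unknown window {window!r}")


def _window_means(
    tc: MeasureTimecourse, positions: range
) -> tuple[float, float]:
    if len(positions) == 0:
        return (float("nan"), float("nan"))
    ent = statistics.fmean(tc.entropy[t] for t in positions)
    err = statistics.fmean(tc.prediction_error[t] for t in positions)
    return ent, err


def condition_timecourses(
    base: Lexicon, triplet: Triplet
) -> dict[tuple[str, str], MeasureTimecourse]:
    """Measure timecourses for all six conditions of one triplet.

    Day-1 stimuli are evaluated against the base lexicon plus this
    triplet's novel word; day-2 stimuli against the base lexicon alone.
    """
    triplet.validate(base)
    day1_lexicon = add_novel_word(base, triplet.novel, triplet.source)
    stimuli = {
        "source": triplet.source.transcription,
        "novel": triplet.novel,
        "baseline": triplet.baseline,
    }
    out: dict[tuple[str, str], MeasureTimecourse] = {}
    for item_type, stimulus in stimuli.items():
        out[(item_type, "day1")] = timecourse(day1_lexicon, stimulus)
        out[(item_type, "day2")] = timecourse(base, stimulus)
    return out


def simulate_conditions(
    base: Lexicon,
    triplets: Sequence[Triplet],
    include_offset: bool = True,
) -> list[ConditionProfile]:
    """Six-condition, three-window profile averaged over triplets.

    For each triplet the stimulus of each item type is measured under the
    day-1 lexicon (novel word present) and the day-2 lexicon (absent);
    entropy and prediction error are averaged within each window and then
    across triplets.  ``include_offset`` controls whether the post-DP
    window includes the end-of-word marker position.
    """
    if not triplets:
        raise DesignError("no triplets supplied")
    sums: dict[tuple[str, str, str], list[tuple[float, float]]] = {
        (it, day, w): [] for it in ITEM_TYPES for day in DAYS for w in WINDOWS
    }
    for triplet in triplets:
        tcs = condition_timecourses(base, triplet)
        for (item_type, day), tc in tcs.items():
            for window in WINDOWS:
                positions = _window_positions(
                    window,
                    triplet.dp_index,
                    triplet.up_index,
                    len(tc),
                    include_offset,
                )
                sums[(item_type, day, window)].append(
                    _window_means(tc, positions)
                )
    profiles = []
    for (item_type, day, window), values in sums.items():
        profiles.append(
            ConditionProfile(
                item_type=item_type,
                day=day,
                window=window,
                mean_entropy=statistics.fmean(v[0] for v in values),
                mean_prediction_error=statistics.fmean(v[1] for v in values),
                n_triplets=len(values),
            )
        )
    return profiles


def profile_lookup(
    profiles: Iterable[ConditionProfile],
) -> dict[tuple[str, str, str], ConditionProfile]:
    """Index profiles by (item_type, day, window)."""
    return {(p.item_type, p.day, p.window): p for p in profiles}


@dataclass(frozen=True)
class InteractionContrasts:
    """The two post-DP prediction-error interactions the design predicts.

    ``lexicality_by_day`` is the cross-over interaction
    ``(novel - source)_day2 - (novel - source)_day1``: training plus
    consolidation reverses which of novel and source is harder to predict.
    ``novelty_by_day`` is ``(baseline - novel)_day1 - (baseline - novel)_day2``:
    only on day 1 does the novel word escape the nonword penalty shared
    with its baseline.  Both are positive under the segment-prediction
    account.  Simple effects are reported as (minuend - subtrahend) pairs.
    """

    lexicality_by_day: float
    novelty_by_day: float
    novel_minus_source_day1: float
    novel_minus_source_day2: float
    baseline_minus_novel_day1: float
    baseline_minus_novel_day2: float


def interaction_contrasts(
    profiles: Iterable[ConditionProfile],
    window: str = "postDP",
) -> InteractionContrasts:
    """Compute both predicted interactions on window-mean prediction error.

    Raises
    ------
    DesignError
        If any of the six condition profiles for ``window`` is missing.
    """
    table = profile_lookup(profiles)

    def err(item_type: str, day: str) -> float:
        key = (item_type, day, window)
        if key not in table:
            raise DesignError(f"missing condition profile: {key}")
        return table[key].mean_prediction_error

    nms_d1 = err("novel", "day1") - err("source", "day1")
    nms_d2 = err("novel", "day2") - err("source", "day2")
    bmn_d1 = err("baseline", "day1") - err("novel", "day1")
    bmn_d2 = err("baseline", "day2") - err("novel", "day2")
    return InteractionContrasts(
        lexicality_by_day=nms_d2 - nms_d1,
        novelty_by_day=bmn_d1 - bmn_d2,
        novel_minus_source_day1=nms_d1,
        novel_minus_source_day2=nms_d2,
        baseline_minus_novel_day1=bmn_d1,
        baseline_minus_novel_day2=bmn_d2,
    )
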