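"""Phonological lexicon: entries, homophone merging, file I/O.

A transcription is an ordered tuple of segment tokens terminated by the
end-of-word marker ``#``.  The marker makes word offset itself a predictable
event, so a word that is a proper prefix of another word (e.g. *cat* vs.
*cats*) still becomes uniquely identifiable at its final position.

Transcriptions default to DISC-style one-character-per-segment strings
(``k@ptIn`` is /k/ /@/ /p/ /t/ /I/ /n/); a space-delimited mode supports
multi-character segment inventories such as ARPABET.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

END_MARKER = "#"

Segment = str
Transcription = tuple[Segment, ...]

DelimiterMode = Literal["single-char", "delimited"]


class LexiconError(ValueError):
    """Raised for malformed lexicon input or invalid lexicon operations."""


def parse_transcription(
    text: str,
    delimiter_mode: DelimiterMode = "single-char",
    append_marker: bool = True,
) -> Transcription:
    """Parse a transcription string into a tuple of segment tokens.

    Parameters
    ----------
    text
        The transcription, e.g. ``"k@ptIn"`` (single-char mode) or
        ``"k ae p t ih n"`` (delimited mode).  Surrounding ``/.../`` slashes
        are stripped for convenience.
    delimiter_mode
        ``"single-char"`` treats each character as one segment (the DISC
        convention); ``"delimited"`` splits on whitespace.
    append_marker
        Append the end-of-word marker ``#`` if not already present.
    """
    text = text.strip()
    if text.startswith("/") and text.endswith("/"):
        text = text[1:-1]
    if delimiter_mode == "single-char":
        segments = tuple(text)
    elif delimiter_mode == "delimited":
        segments = tuple(text.split())
    else:  # pragma: no cover - guarded by Literal type
        raise LexiconError(f"unknown delimiter mode: {delimiter_mode!r}")
    if any(not s or s.isspace() or "\t" in s for s in segments):
        raise LexiconError(f"transcription contains blank token: {text!r}")
    if END_MARKER in segments:
        if segments.count(END_MARKER) != 1 or segments[-1] != END_MARKER:
            raise LexiconError(
                f"end marker must occur exactly once, last: {text!r}"
            )
    elif append_marker:
        segments = segments + (END_MARKER,)
    if len(segments) < 2:
        raise LexiconError(f"empty transcription: {text!r}")
    return segments


def format_transcription(
    transcription: Sequence[Segment],
    delimiter_mode: DelimiterMode = "single-char",
) -> str:
    """Inverse of :func:`parse_transcription` (end marker included)."""
    if delimiter_mode == "single-char":
        return "".join(transcription)
    return " ".join(transcription)


@dataclass(frozen=True)
class LexicalEntry:
    """One word: spelling, segmental transcription, frequency per million."""

    orthography: str
    transcription: Transcription
    frequency: float
    monomorphemic: bool = True

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise LexiconError(
                f"negative frequency for {self.orthography!r}: {self.frequency}"
            )
        if not self.transcription or self.transcription[-1] != END_MARKER:
            raise LexiconError(
                f"transcription must end with {END_MARKER!r}: "
                f"{self.transcription!r}"
            )


@dataclass(frozen=True)
class Lexicon:
    """Homophone-merged collection of entries keyed by transcription."""

    entries: dict[Transcription, LexicalEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, entry in self.entries.items():
            if key != entry.transcription:
                raise LexiconError(
                    f"entry keyed by {key!r} has transcription "
                    f"{entry.transcription!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexicalEntry]:
        return iter(self.entries.values())

    def __contains__(self, transcription: Transcription) -> bool:
        return tuple(transcription) in self.entries

    @property
    def total_frequency(self) -> float:
        return sum(e.frequency for e in self.entries.values())

    def prefix_matches(self, prefix: Sequence[Segment]) -> list[LexicalEntry]:
        """Entries whose transcription begins with ``prefix``."""
        prefix = tuple(prefix)
        n = len(prefix)
        return [
            e for e in self.entries.values() if e.transcription[:n] == prefix
        ]


def merge_homophones(entries: Iterable[LexicalEntry]) -> Lexicon:
    """Collapse entries sharing a transcription into one, summing frequency.

    The orthography of the highest-frequency member is retained purely as a
    label; all measures depend only on transcription and frequency.  An
    entry is flagged monomorphemic only if every merged member is.
    """
    merged: dict[Transcription, LexicalEntry] = {}
    for entry in entries:
        key = entry.transcription
        if key in merged:
            old = merged[key]
            label = (
                old.orthography
                if old.frequency >= entry.frequency
                else entry.orthography
            )
            merged[key] = LexicalEntry(
                orthography=label,
                transcription=key,
                frequency=old.frequency + entry.frequency,
                monomorphemic=old.monomorphemic and entry.monomorphemic,
            )
        else:
            merged[key] = entry
    return Lexicon(entries=merged)


def filter_monomorphemic(lexicon: Lexicon) -> Lexicon:
    """Restrict the lexicon to entries flagged monomorphemic."""
    return Lexicon(
        entries={
            k: e for k, e in lexicon.entries.items() if e.monomorphemic
        }
    )


def add_novel_word(
    lexicon: Lexicon,
    novel: Sequence[Segment],
    source: LexicalEntry,
    orthography: str | None = None,
) -> Lexicon:
    """Return a new lexicon with a novel word at its source word's frequency.

    A freshly learned (and consolidated) novel word has no corpus frequency;
    it inherits the frequency of the existing word it was derived from,
    which fixes the amount of learning assumed.

    Raises
    ------
    LexiconError
        If ``source`` is not a member of ``lexicon`` or ``novel`` is already
        present (a silent homophone merge would corrupt the manipulation).
    """
    novel = tuple(novel)
    if source.transcription not in lexicon.entries:
        raise LexiconError(
            f"source word {source.orthography!r} not in lexicon"
        )
    if novel in lexicon.entries:
        raise LexiconError(
            f"novel transcription already present: {novel!r}"
        )
    entry = LexicalEntry(
        orthography=orthography or format_transcription(novel[:-1]),
        transcription=novel,
        frequency=source.frequency,
        monomorphemic=True,
    )
    entries = dict(lexicon.entries)
    entries[novel] = entry
    return Lexicon(entries=entries)


def read_lexicon(
    path: str | Path,
    delimiter_mode: DelimiterMode = "single-char",
    monomorphemic_only: bool = False,
    frequency_floor: float | None = None,
) -> Lexicon:
    """Read a TSV lexicon and return it homophone-merged.

    Format: UTF-8, one word per row, ``orthography<TAB>transcription<TAB>
    frequency_per_million[<TAB>monomorphemic(0/1)]``.  Lines starting with
    ``#`` and blank lines are ignored.  The end-of-word marker is appended
    to each transcription if absent.

    ``frequency_floor``, if given, replaces any smaller frequency at read
    time (no smoothing is applied by default).

    Raises
    ------
    LexiconError
        With the 1-based line number of every malformed row.
    """
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    entries: list[LexicalEntry] = []
    problems: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                problems.append(f"line {lineno}: expected >=3 columns")
                continue
            orth, trans_text, freq_text = fields[0], fields[1], fields[2]
            try:
                transcription = parse_transcription(
                    trans_text, delimiter_mode=delimiter_mode
                )
            except LexiconError as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            try:
                frequency = float(freq_text)
            except ValueError:
                problems.append(
                    f"line {lineno}: non-numeric frequency {freq_text!r}"
                )
                continue
            if frequency < 0:
                problems.append(f"line {lineno}: negative frequency")
                continue
            mono = True
            if len(fields) >= 4 and fields[3].strip():
                mono = fields[3].strip() not in ("0", "false", "False")
            if frequency_floor is not None:
                frequency = max(frequency, frequency_floor)
            entries.append(
                LexicalEntry(orth, transcription, frequency, mono)
            )
    if problems:
        raise LexiconError(
            f"{path}: {len(problems)} malformed row(s):\n  "
            + "\n  ".join(problems)
        )
    lexicon = merge_homophones(entries)
    if monomorphemic_only:
        lexicon = filter_monomorphemic(lexicon)
    return lexicon


def write_lexicon(
    lexicon: Lexicon,
    path: str | Path,
    delimiter_mode: DelimiterMode = "single-char",
) -> None:
    """Write a lexicon in the same TSV dialect :func:`read_lexicon` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# orthography\ttranscription\tfrequency_per_million\tmonomorphemic\n")
        for entry in lexicon:
            fh.write(
                "\t".join(
                    (
                        entry.orthography,
                        format_transcription(entry.transcription, delimiter_mode),
                        repr(entry.frequency),
                        "1" if entry.monomorphemic else "0",
                    )
                )
                + "\n"
            )


def entry(lexicon: Lexicon, transcription: Sequence[Segment]) -> LexicalEntry:
    """Look up an entry by transcription, raising if absent."""
    key = tuple(transcription)
    try:
        return lexicon.entries[key]
    except KeyError:
        raise LexiconError(f"no entry with transcription {key!r}") from None


def with_frequency(entry: LexicalEntry, frequency: float) -> LexicalEntry:
    """Copy of ``entry`` with a different frequency."""
    return replace(entry, frequency=frequency)
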