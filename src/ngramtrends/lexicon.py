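"""Construct word lists: loading, validation, filtering, inflection queries.

A lexicon is the curated word list for one psychological construct
(e.g. anxiety, depression, digitalization, or the religion control) in one
corpus language.  Curation outcomes of the manual steps that produced the
published lists — translation, back-translation, double-meaning screening —
are carried as *data* (include flags and exclusion reasons) in an editable
TSV file; this module never attempts automated translation or synonym
expansion.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ExclusionReason",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "DominanceReport",
    "load_lexicon",
    "filtered_words",
    "inflection_terms",
    "dominance_check",
]

INFLECTION_TAG = "_INF"


class LexiconError(ValueError):
    """Malformed, inconsistent or unusable word-list content."""


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    DOUBLE_MEANING = "double_meaning"
    UNTRANSLATABLE = "untranslatable"
    BROADER_SEMANTIC = "broader_semantic"
    OTHER = "other"


@dataclass(frozen=True)
class LexiconEntry:
    """One candidate word with its curation outcome.

    ``include`` is true iff the word survived curation; an excluded word
    must carry a non-``none`` exclusion reason and vice versa.
    """

    word: str
    include: bool
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    notes: str = ""
    inflections: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.word:
            raise LexiconError("empty word")
        if any(ch.isspace() for ch in self.word):
            raise LexiconError(f"word {self.word!r} contains whitespace (1-grams only)")
        if self.include and self.exclusion_reason is not ExclusionReason.NONE:
            raise LexiconError(
                f"word {self.word!r}: include=true conflicts with "
                f"exclusion_reason={self.exclusion_reason.value}"
            )
        if not self.include and self.exclusion_reason is ExclusionReason.NONE:
            raise LexiconError(
                f"word {self.word!r}: excluded entries need an exclusion_reason"
            )


@dataclass(frozen=True)
class Lexicon:
    """Word list for one (construct, language) pair, in file order."""

    construct: str
    language: str
    entries: tuple[LexiconEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise LexiconError(
                f"{self.construct}/{self.language}: no entries"
            )
        seen: dict[str, str] = {}
        for e in self.entries:
            key = e.word.casefold()
            if key in seen:
                raise LexiconError(
                    f"{self.construct}/{self.language}: duplicate word "
                    f"{e.word!r} (case-folded clash with {seen[key]!r})"
                )
            seen[key] = e.word

    @property
    def usable(self) -> bool:
        """Whether at least one entry survives filtering."""
        return any(e.include for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_row(row: dict, lineno: int) -> LexiconEntry:
    word = (row.get("word") or "").strip()
    raw_inc = (row.get("include") or "").strip().casefold()
    if raw_inc not in _BOOL:
        raise LexiconError(f"line {lineno}: include must be true/false, got {raw_inc!r}")
    raw_reason = (row.get("exclusion_reason") or "none").strip() or "none"
    try:
        reason = ExclusionReason(raw_reason)
    except ValueError:
        raise LexiconError(
            f"line {lineno}: unknown exclusion_reason {raw_reason!r}"
        ) from None
    raw_infl = (row.get("inflections") or "").strip()
    inflections = tuple(s.strip() for s in raw_infl.split(",") if s.strip())
    try:
        return LexiconEntry(
            word=word,
            include=_BOOL[raw_inc],
            exclusion_reason=reason,
            notes=(row.get("notes") or "").strip(),
            inflections=inflections,
        )
    except LexiconError as exc:
        raise LexiconError(f"line {lineno}: {exc}") from None


def load_lexicon(path: str | Path, construct: str, language: str) -> Lexicon:
    """Load a word-list TSV (columns word, include, exclusion_reason, notes,
    optional inflections) into a validated :class:`Lexicon`.

    Malformed rows are reported with their line numbers; all problems found
    are raised together in a single :class:`LexiconError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"word-list file not found: {path}")
    entries: list[LexiconEntry] = []
    problems: list[str] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "word" not in reader.fieldnames:
            raise LexiconError(f"{path}: missing header with a 'word' column")
        for row in reader:
            try:
                entries.append(_parse_row(row, reader.line_num))
            except LexiconError as exc:
                problems.append(str(exc))
    if problems:
        raise LexiconError(f"{path}: " + "; ".join(problems))
    if not entries:
        raise LexiconError(f"{path}: no entries")
    return Lexicon(construct=construct, language=language, entries=tuple(entries))


def filtered_words(lex: Lexicon) -> list[str]:
    """The included words, in file order.  Errors if none survive."""
    words = [e.word for e in lex.entries if e.include]
    if not words:
        raise LexiconError(
            f"{lex.construct}/{lex.language}: no included words — lexicon unusable"
        )
    return words


def inflection_terms(lex: Lexicon) -> list[str]:
    """Ngram Viewer inflection-expansion queries: each included word + ``_INF``."""
    return [w + INFLECTION_TAG for w in filtered_words(lex)]


@dataclass(frozen=True)
class DominanceReport:
    base_word: str
    dominant_form: str
    is_base_dominant: bool
    totals: dict = field(default_factory=dict)


def dominance_check(word: str, inflection_panel) -> DominanceReport:
    """Identify the most frequent inflected form of ``word``.

    ``inflection_panel`` is a :class:`~ngramtrends.ngram_io.FrequencyPanel`
    restricted to the word's inflection series.  The dominant form is the
    one with the largest frequency summed over the panel's year range; exact
    ties break lexicographically so the result is deterministic and
    independent of column order.
    """
    totals = {w: float(s) for w, s in inflection_panel.data.sum(axis=0).items()}
    if not totals:
        raise LexiconError(f"{word!r}: empty inflection panel")
    best = min(totals, key=lambda form: (-totals[form], form))
    return DominanceReport(
        base_word=word,
        dominant_form=best,
        is_base_dominant=(best.casefold() == word.casefold()),
        totals=totals,
    )
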