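"""VAD emotion lexicons.

A VAD lexicon maps words to points in the valence-arousal-dominance unit
cube, following the tab-separated layout popularised by NRC-VAD
(``term<TAB>valence<TAB>arousal<TAB>dominance``, one entry per line, an
optional header).  The same lexicon object serves two roles in this
package: transforming categorical emotion labels into dimensional ones,
and word-level lookup inside the rule-based scorer.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "VADScore",
    "EmotionLexicon",
    "LexiconParseError",
    "read_lexicon",
    "write_lexicon",
]


class LexiconParseError(ValueError):
    """Raised for a malformed lexicon line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class VADScore:
    """A point in the VAD unit cube.

    valence : pleasantness, 0 = maximally negative, 1 = maximally positive
    arousal : activation/intensity, 0 = calm, 1 = excited
    dominance : sense of control, 0 = controlled, 1 = in control
    """

    valence: float
    arousal: float
    dominance: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal", "dominance"):
            x = getattr(self, name)
            try:
                x = float(x)
            except (TypeError, ValueError):
                raise ValueError(f"{name} must be a finite number, got {x!r}") from None
            if not math.isfinite(x):
                raise ValueError(f"{name} must be a finite number, got {x!r}")
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {x!r}")
            object.__setattr__(self, name, x)  # plain float, so repr round-trips

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.valence, self.arousal, self.dominance)

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())


@dataclass
class EmotionLexicon:
    """Term -> :class:`VADScore` dictionary with case-insensitive lookup.

    Terms are lowercased on insertion; lookups lowercase the query, so
    mixed-case utterance tokens match the (lowercase) lexicon vocabulary.
    Multi-word entries are stored verbatim and reachable only through an
    exact-term :meth:`lookup`; the rule scorer matches single tokens.
    """

    name: str = "lexicon"
    entries: dict[str, VADScore] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, VADScore] = {}
        for term, score in self.entries.items():
            key = self._normalise(term)
            if not key:
                raise ValueError("lexicon terms must be non-empty")
            clean[key] = score
        self.entries = clean

    @staticmethod
    def _normalise(term: str) -> str:
        return term.strip().lower()

    def add(self, term: str, score: VADScore) -> None:
        key = self._normalise(term)
        if not key:
            raise ValueError("lexicon terms must be non-empty")
        self.entries[key] = score

    def lookup(self, term: str) -> VADScore | None:
        """Return the score for ``term`` (case-insensitive) or ``None``.

        Absent terms return ``None`` explicitly — never a default score.
        """
        return self.entries.get(self._normalise(term))

    def __contains__(self, term: str) -> bool:
        return self._normalise(term) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EmotionLexicon):
            return NotImplemented
        return self.entries == other.entries

    def terms(self) -> list[str]:
        return list(self.entries)


def _parse_score(raw: str, line_number: int, column: str) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise LexiconParseError(line_number, f"non-numeric {column} {raw!r}") from None
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise LexiconParseError(line_number, f"{column} {raw!r} outside [0, 1]")
    return value


def read_lexicon(stream: IO[str] | str, name: str = "lexicon") -> EmotionLexicon:
    """Parse a tab-separated term/valence/arousal/dominance lexicon.

    ``stream`` may be an open text stream or a path.  A header line is
    auto-detected: if fields 2-4 of the first line are not all numeric it
    is skipped.  Duplicate terms: the last occurrence wins and a warning
    is logged (tolerant ingestion of concatenated lexicons).

    Raises :class:`LexiconParseError` for a wrong field count, a
    non-numeric score, or a score outside [0, 1], naming the line.
    """
    if isinstance(stream, str):
        with open(stream, encoding="utf-8") as fh:
            return read_lexicon(fh, name=name)

    lexicon = EmotionLexicon(name=name)
    for line_number, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise LexiconParseError(
                line_number, f"expected 4 tab-separated fields, got {len(fields)}"
            )
        term = fields[0].strip()
        if line_number == 1 and not _all_numeric(fields[1:]):
            continue  # header
        if not term:
            raise LexiconParseError(line_number, "empty term")
        score = VADScore(
            _parse_score(fields[1], line_number, "valence"),
            _parse_score(fields[2], line_number, "arousal"),
            _parse_score(fields[3], line_number, "dominance"),
        )
        key = EmotionLexicon._normalise(term)
        if key in lexicon.entries:
            logger.warning(
                "lexicon %s: duplicate term %r at line %d overwrites earlier entry",
                name, key, line_number,
            )
        lexicon.entries[key] = score
    return lexicon


def _all_numeric(fields: list[str]) -> bool:
    for f in fields:
        try:
            float(f)
        except ValueError:
            return False
    return True


def write_lexicon(lexicon: EmotionLexicon, stream: IO[str] | str | None = None) -> str | None:
    """Emit the tab-separated layout :func:`read_lexicon` accepts.

    Round-trip guarantee: ``read_lexicon(write_lexicon(L)) == L``.
    With ``stream=None`` the serialised text is returned instead.
    """
    if stream is None:
        buf = io.StringIO()
        write_lexicon(lexicon, buf)
        return buf.getvalue()
    if isinstance(stream, str):
        with open(stream, "w", encoding="utf-8") as fh:
            write_lexicon(lexicon, fh)
        return None
    for term, score in lexicon.entries.items():
        stream.write(
            f"{term}\t{score.valence!r}\t{score.arousal!r}\t{score.dominance!r}\n"
        )
    return None
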