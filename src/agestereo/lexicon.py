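"""Stereotype content lexicon: word -> (dimension, subdimension, valence).

The Stereotype Content Model places social perception on two axes, warmth and
competence; each splits into two subdimensions (warmth: sociability and
morality; competence: ability and assertiveness), and each subdimension has
positive and negative word classes.  A word may carry more than one entry —
"play", for instance, is a positive sociability term but, through its sense
"to deceive", also a negative morality term.

Lexicons are read from delimited text with columns
``word, dimension, subdimension, valence``; a small built-in seed set is
provided for tests and synthetic studies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "WARMTH",
    "COMPETENCE",
    "SUBDIMENSIONS",
    "DIMENSION_OF",
    "LexiconEntry",
    "ScmLexicon",
    "load_lexicon",
    "builtin_lexicon",
]

WARMTH = "warmth"
COMPETENCE = "competence"
SUBDIMENSIONS: tuple[str, ...] = ("sociability", "morality", "ability", "assertiveness")
DIMENSION_OF: dict[str, str] = {
    "sociability": WARMTH,
    "morality": WARMTH,
    "ability": COMPETENCE,
    "assertiveness": COMPETENCE,
}
#: All eight (subdimension, valence) cells in canonical order.
CELLS: tuple[tuple[str, int], ...] = tuple(
    (sub, val) for sub in SUBDIMENSIONS for val in (+1, -1)
)


@dataclass(frozen=True)
class LexiconEntry:
    word: str  # lowercase lemma
    dimension: str  # warmth | competence
    subdimension: str  # sociability | morality | ability | assertiveness
    valence: int  # +1 | -1

    def __post_init__(self) -> None:
        if self.subdimension not in DIMENSION_OF:
            raise ValueError(f"unknown subdimension {self.subdimension!r}")
        if DIMENSION_OF[self.subdimension] != self.dimension:
            raise ValueError(
                f"subdimension {self.subdimension!r} is inconsistent with "
                f"dimension {self.dimension!r}"
            )
        if self.valence not in (+1, -1):
            raise ValueError(f"valence must be +1 or -1, got {self.valence}")
        if self.word != self.word.lower() or not self.word:
            raise ValueError(f"word must be a non-empty lowercase lemma: {self.word!r}")


class ScmLexicon:
    """Immutable collection of :class:`LexiconEntry`.

    A (word, subdimension, valence) triple may appear at most once; a word
    may appear under several subdimensions.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        entries = list(entries)
        seen = set()
        for e in entries:
            key = (e.word, e.subdimension, e.valence)
            if key in seen:
                raise ValueError(f"duplicate lexicon entry {key}")
            seen.add(key)
        self.entries: tuple[LexiconEntry, ...] = tuple(entries)
        self._by_word: dict[str, tuple[LexiconEntry, ...]] = {}
        by_word: dict[str, list[LexiconEntry]] = {}
        for e in entries:
            by_word.setdefault(e.word, []).append(e)
        self._by_word = {w: tuple(v) for w, v in by_word.items()}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def lookup(self, word: str) -> tuple[LexiconEntry, ...]:
        """All entries for a word (empty tuple if absent)."""
        return self._by_word.get(word, ())

    def words(self) -> tuple[str, ...]:
        return tuple(self._by_word)

    def cell_words(self, subdimension: str, valence: int) -> tuple[str, ...]:
        """Words of one (subdimension, valence) cell, in entry order."""
        return tuple(
            e.word
            for e in self.entries
            if e.subdimension == subdimension and e.valence == valence
        )

    def dimension_entries(self, dimension: str) -> tuple[LexiconEntry, ...]:
        return tuple(e for e in self.entries if e.dimension == dimension)


def load_lexicon(path: str | Path, delimiter: str | None = None) -> ScmLexicon:
    """Read a lexicon from delimited text (CSV/TSV, sniffed if not given).

    Expected columns: ``word, dimension, subdimension, valence`` (header row
    required; valence accepts ``+1/-1/1/positive/negative``).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if delimiter is None:
            delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        entries = []
        for row in reader:
            val_raw = row["valence"].strip().lower()
            valence = {
                "+1": 1, "1": 1, "positive": 1, "pos": 1,
                "-1": -1, "negative": -1, "neg": -1,
            }.get(val_raw)
            if valence is None:
                raise ValueError(f"unparseable valence {row['valence']!r} in {path}")
            entries.append(
                LexiconEntry(
                    word=row["word"].strip().lower(),
                    dimension=row["dimension"].strip().lower(),
                    subdimension=row["subdimension"].strip().lower(),
                    valence=valence,
                )
            )
    return ScmLexicon(entries)


# Built-in seed set.  Small by design: enough words per cell to train the
# template scorer and drive the synthetic generator.  "play" is deliberately
# listed under both (sociability, +) and (morality, -) to exercise
# multi-category counting.
_SEED: dict[tuple[str, int], tuple[str, ...]] = {
    ("sociability", +1): (
        "friendly", "warm", "sociable", "outgoing", "cheerful", "affectionate",
        "playful", "play",
    ),
    ("sociability", -1): (
        "cold", "distant", "unfriendly", "withdrawn", "aloof", "lonely",
    ),
    ("morality", +1): (
        "honest", "fair", "trustworthy", "sincere", "loyal", "generous",
        "kind", "caring",
    ),
    ("morality", -1): (
        "dishonest", "deceitful", "selfish", "cruel", "unfair", "play",
    ),
    ("ability", +1): (
        "intelligent", "capable", "skilled", "competent", "wise",
        "knowledgeable", "clever", "able",
    ),
    ("ability", -1): (
        "incompetent", "clumsy", "foolish", "incapable", "unskilled",
    ),
    ("assertiveness", +1): (
        "confident", "ambitious", "assertive", "determined", "energetic",
        "decisive", "bold", "driven",
    ),
    ("assertiveness", -1): (
        "passive", "timid", "hesitant", "submissive", "insecure", "meek",
    ),
}


def builtin_lexicon() -> ScmLexicon:
    """The built-in demo seed lexicon (48 entries, 8 cells)."""
    entries = [
        LexiconEntry(word=w, dimension=DIMENSION_OF[sub], subdimension=sub, valence=val)
        for (sub, val), words in _SEED.items()
        for w in words
    ]
    return ScmLexicon(entries)
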