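"""Lexicon-based word counts for the four stereotype subdimensions.

Pipeline: extract noun/adjective lemmas per age, find each age's highly
common words (a cumulative-frequency reading of Zipf's law of common terms),
drop words common in more than ``max_ages`` ages (likely model boilerplate
rather than stereotype content), then count occurrences of the retained
lemmas against the stereotype lexicon, split by (subdimension, valence).
A lemma with several lexicon entries increments every matching cell.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .lexicon import CELLS, ScmLexicon
from .postag import content_lemmas

__all__ = [
    "SubdimensionCountTable",
    "VocabularyFilterReport",
    "extract_content_words",
    "zipf_common_terms",
    "exclude_cross_age_common",
    "count_subdimensions",
]

#: Column order of the exported count table (per-subdimension positive/negative).
TABLE_COLUMNS = [
    "age",
    "total_word_count",
    "sociability_positive",
    "sociability_negative",
    "morality_positive",
    "morality_negative",
    "ability_positive",
    "ability_negative",
    "assertiveness_positive",
    "assertiveness_negative",
]


@dataclass
class VocabularyFilterReport:
    """Words excluded for being common across too many ages."""

    excluded_words: list[tuple[str, int]]  # (word, number of ages it was common in)
    threshold_ages: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded_words, columns=["word", "n_ages"])


@dataclass
class SubdimensionCountTable:
    """Per-age totals and 8-cell (subdimension x valence) counts."""

    ages: list[int]
    total_word_count: dict[int, int]
    counts: dict[int, dict[tuple[str, int], int]]

    def __post_init__(self) -> None:
        for age in self.ages:
            for cell, c in self.counts[age].items():
                if c < 0 or c > self.total_word_count[age]:
                    raise ValueError(
                        f"count {c} for {cell} at age {age} exceeds total "
                        f"{self.total_word_count[age]}"
                    )

    def cell(self, age: int, subdimension: str, valence: int) -> int:
        return self.counts[age][(subdimension, valence)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for age in self.ages:
            row = {"age": age, "total_word_count": self.total_word_count[age]}
            for sub, val in CELLS:
                name = f"{sub}_{'positive' if val > 0 else 'negative'}"
                row[name] = self.counts[age][(sub, val)]
            rows.append(row)
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def extract_content_words(text: str) -> list[str]:
    """Noun/adjective lemmas of ``text`` (lowercased, in occurrence order)."""
    if not text:
        raise ValueError("text must be non-empty")
    return content_lemmas(text)


def zipf_common_terms(
    lemmas_by_age: dict[int, list[str]], top_fraction: float = 0.8
) -> dict[int, set[str]]:
    """Each age's most common words by a cumulative-frequency prefix rule.

    Words are ranked by frequency (ties by lexicographic order); the common
    set is the smallest rank prefix whose cumulative frequency reaches
    ``top_fraction`` of the age's tokens, extended to include all words tied
    at the cut frequency.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must lie in (0, 1]")
    out: dict[int, set[str]] = {}
    for age, lemmas in lemmas_by_age.items():
        if not lemmas:
            raise ValueError(f"age {age} has an empty lemma multiset")
        freq = Counter(lemmas)
        ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
        total = len(lemmas)
        target = top_fraction * total
        common: set[str] = set()
        cum = 0
        cut_freq = None
        for word, f in ranked:
            if cum >= target and f != cut_freq:
                break
            common.add(word)
            cum += f
            cut_freq = f
        out[age] = common
    return out


def exclude_cross_age_common(
    common_sets: dict[int, set[str]], max_ages: int = 6
) -> tuple[dict[int, set[str]], VocabularyFilterReport]:
    """Remove words common in strictly more than ``max_ages`` ages.

    Removal applies to every age's vocabulary.  Returns the retained
    vocabulary per age and a report of exclusions with their age spans.
    """
    if max_ages < 0:
        raise ValueError("max_ages must be >= 0")
    spans = Counter()
    for words in common_sets.values():
        spans.update(words)
    excluded = {w for w, n in spans.items() if n > max_ages}
    retained = {age: words - excluded for age, words in common_sets.items()}
    report = VocabularyFilterReport(
        excluded_words=sorted((w, spans[w]) for w in excluded),
        threshold_ages=max_ages,
    )
    return retained, report


def count_subdimensions(
    lemmas_by_age: dict[int, list[str]],
    retained_vocab: dict[int, set[str]],
    lexicon: ScmLexicon,
    totals_by_age: dict[int, int] | None = None,
) -> SubdimensionCountTable:
    """Tally retained lemmas against the lexicon, per age and cell.

    ``totals_by_age`` supplies the raw token count of each age's filtered
    sentences (all tokens, not only nouns/adjectives) for the table's total
    column; when omitted, the lemma multiset size is used instead.
    """
    if set(lemmas_by_age) != set(retained_vocab):
        raise ValueError("lemmas_by_age and retained_vocab must share the same ages")
    ages = sorted(lemmas_by_age)
    totals: dict[int, int] = {}
    counts: dict[int, dict[tuple[str, int], int]] = {}
    for age in ages:
        totals[age] = (
            totals_by_age[age] if totals_by_age is not None else len(lemmas_by_age[age])
        )
        cells = {cell: 0 for cell in CELLS}
        vocab = retained_vocab[age]
        for lemma in lemmas_by_age[age]:
            if lemma not in vocab:
                continue
            for entry in lexicon.lookup(lemma):
                cells[(entry.subdimension, entry.valence)] += 1
        counts[age] = cells
    return SubdimensionCountTable(ages=ages, total_word_count=totals, counts=counts)
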