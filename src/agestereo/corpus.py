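"""Corpus construction and sentence-level preprocessing.

The study design collects free-text personality descriptions from a language
model with the prompt "Describe the personality of a [AGE]-year-old person.",
varying AGE over 10..90 in steps of 10, 100 responses per age.  Responses are
split into sentences, and three filters are applied before any analysis:

1. the first and last sentence of every response are dropped (boilerplate
   opening/closing disclaimers),
2. sentences of three words or fewer are dropped (short sentences embed
   poorly),
3. sentences ending with a colon are dropped (list headers such as
   "Here are some common characteristics:").
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

__all__ = [
    "DEFAULT_PROMPT_TEMPLATE",
    "AGE_PLACEHOLDER",
    "CollectionConfig",
    "Sentence",
    "TextSample",
    "TextProvider",
    "ConfigurationError",
    "CollectionError",
    "render_prompt",
    "split_sentences",
    "filter_sentences",
    "collect_corpus",
    "word_count",
    "tokenize",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_sentences_jsonl",
]

AGE_PLACEHOLDER = "[AGE]"
DEFAULT_PROMPT_TEMPLATE = "Describe the personality of a [AGE]-year-old person."

#: Default study design: ages 10..90 in steps of 10, 100 responses per age,
#: sampled at temperature 1.0, top_p 1.0, at most 2048 tokens per response.
DEFAULT_AGES: tuple[int, ...] = tuple(range(10, 100, 10))


class ConfigurationError(ValueError):
    """Invalid collection configuration (e.g. malformed prompt template)."""


class CollectionError(RuntimeError):
    """A provider request failed; partial corpora are never returned."""


class TextProvider(Protocol):
    """Anything that can answer a prompt with generated text."""

    def generate(
        self, prompt: str, temperature: float, top_p: float, max_tokens: int
    ) -> str: ...


@dataclass(frozen=True)
class CollectionConfig:
    """Parameters of a corpus collection run."""

    prompt_template: str = DEFAULT_PROMPT_TEMPLATE
    ages: tuple[int, ...] = DEFAULT_AGES
    responses_per_age: int = 100
    temperature: float = 1.0
    top_p: float = 1.0
    max_tokens: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prompt_template.count(AGE_PLACEHOLDER) != 1:
            raise ConfigurationError(
                f"prompt template must contain {AGE_PLACEHOLDER!r} exactly once: "
                f"{self.prompt_template!r}"
            )
        ages = tuple(self.ages)
        object.__setattr__(self, "ages", ages)
        if not ages or any(b <= a for a, b in zip(ages, ages[1:])):
            raise ConfigurationError(f"ages must be strictly increasing: {ages}")
        if self.responses_per_age < 1:
            raise ConfigurationError("responses_per_age must be >= 1")
        if self.temperature < 0:
            raise ConfigurationError("temperature must be >= 0")
        if not (0 < self.top_p <= 1):
            raise ConfigurationError("top_p must be in (0, 1]")
        if self.max_tokens < 1:
            raise ConfigurationError("max_tokens must be >= 1")


@dataclass(frozen=True)
class Sentence:
    text: str
    word_count: int
    position_index: int
    is_first: bool
    is_last: bool
    ends_with_colon: bool


@dataclass
class TextSample:
    """One model response, tagged with the prompted age."""

    sample_id: str
    age: int
    raw_text: str
    sentences: list[Sentence] = field(default_factory=list)


def render_prompt(template: str, age: int) -> str:
    """Substitute the age into the prompt template.

    Raises :class:`ConfigurationError` if the placeholder is missing or
    duplicated, or if ``age`` is not a positive integer.
    """
    if template.count(AGE_PLACEHOLDER) != 1:
        raise ConfigurationError(
            f"prompt template must contain {AGE_PLACEHOLDER!r} exactly once: {template!r}"
        )
    if age <= 0:
        raise ConfigurationError(f"age must be positive, got {age}")
    return template.replace(AGE_PLACEHOLDER, str(age))


_STRIP_CHARS = string.punctuation + "‘’“”–—…"


def tokenize(text: str) -> list[str]:
    """Whitespace tokens with surrounding punctuation stripped, lowercased.

    Hyphenated forms count as one token ("40-year-old" stays whole because
    only *surrounding* punctuation is stripped).
    """
    out = []
    for tok in text.split():
        tok = tok.strip(_STRIP_CHARS).lower()
        if tok:
            out.append(tok)
    return out


def word_count(text: str) -> int:
    """Number of whitespace tokens that are non-empty after punctuation strip."""
    return len(tokenize(text))


# Terminal punctuation ends a sentence unless it closes a known abbreviation.
_ABBREVIATIONS = {
    "e.g", "i.e", "etc", "vs", "dr", "mr", "mrs", "ms", "prof", "st",
    "approx", "no", "al",
}
_TERMINAL_RE = re.compile(r"[.!?]+[\"')\]]*(?=\s|$)")


def _split_line(line: str) -> list[str]:
    """Split one line into sentences at terminal punctuation."""
    pieces: list[str] = []
    start = 0
    for m in _TERMINAL_RE.finditer(line):
        candidate = line[start : m.end()]
        # abbreviation guard: look at the token preceding the terminal mark
        prefix = line[start : m.start()]
        last_tok = prefix.rsplit(None, 1)[-1] if prefix.split() else ""
        last_tok = last_tok.rstrip(".").lstrip("(\"'").lower()
        # guard abbreviations and bare list-enumeration numbers ("1. ...")
        if last_tok in _ABBREVIATIONS or last_tok.isdigit():
            continue
        piece = candidate.strip()
        if piece:
            pieces.append(piece)
        start = m.end()
    tail = line[start:].strip()
    if tail:
        pieces.append(tail)
    return pieces


def split_sentences(raw_text: str) -> list[Sentence]:
    """Rule-based sentence splitter.

    Sentences end at terminal punctuation (``. ! ?``, with a small
    abbreviation guard list) or at a newline; newline splitting is what keeps
    list items and colon-terminated list headers as separate sentences.
    Returns an empty list for empty input.
    """
    texts: list[str] = []
    for line in raw_text.splitlines():
        line = line.strip()
        if line:
            texts.extend(_split_line(line))
    n = len(texts)
    return [
        Sentence(
            text=t,
            word_count=word_count(t),
            position_index=i,
            is_first=(i == 0),
            is_last=(i == n - 1),
            ends_with_colon=t.rstrip().endswith(":"),
        )
        for i, t in enumerate(texts)
    ]


def filter_sentences(sentences: Sequence[Sentence]) -> list[Sentence]:
    """Apply the three preprocessing filters to one response's sentences.

    Order: (i) drop the first and last sentence, (ii) drop sentences with
    three words or fewer, (iii) drop sentences ending with a colon.  Relative
    order is preserved and sentence text is never altered.  A response whose
    sentences all fail yields an empty list.
    """
    kept = [s for s in sentences if not (s.is_first or s.is_last)]
    kept = [s for s in kept if s.word_count > 3]
    kept = [s for s in kept if not s.ends_with_colon]
    return kept


def filter_report(sentences: Sequence[Sentence]) -> dict[str, int]:
    """Per-rule removal counts for one response (audit logging)."""
    positional = [s for s in sentences if s.is_first or s.is_last]
    rest = [s for s in sentences if not (s.is_first or s.is_last)]
    short = [s for s in rest if s.word_count <= 3]
    rest = [s for s in rest if s.word_count > 3]
    colon = [s for s in rest if s.ends_with_colon]
    return {
        "total": len(sentences),
        "removed_positional": len(positional),
        "removed_short": len(short),
        "removed_colon": len(colon),
        "kept": len(rest) - len(colon),
    }


def collect_corpus(provider: TextProvider, config: CollectionConfig) -> list[TextSample]:
    """Collect ``len(ages) * responses_per_age`` responses through a provider.

    Sample ids encode age and replicate (``age40_r007``).  Raw provider text
    is stored unmodified; sentences are split eagerly.  Any provider failure
    aborts the whole collection with a :class:`CollectionError` naming the
    failed request — a partial corpus is never returned silently.
    """
    samples: list[TextSample] = []
    for age in config.ages:
        prompt = render_prompt(config.prompt_template, age)
        for rep in range(config.responses_per_age):
            try:
                text = provider.generate(
                    prompt,
                    temperature=config.temperature,
                    top_p=config.top_p,
                    max_tokens=config.max_tokens,
                )
            except Exception as exc:  # noqa: BLE001 - provider contract is opaque
                raise CollectionError(
                    f"provider failed for age={age}, replicate={rep}: {exc}"
                ) from exc
            samples.append(
                TextSample(
                    sample_id=f"age{age:02d}_r{rep:03d}",
                    age=age,
                    raw_text=text,
                    sentences=split_sentences(text),
                )
            )
    return samples


# ---------------------------------------------------------------------------
# JSON-Lines persistence


def write_corpus_jsonl(samples: Iterable[TextSample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in samples:
            fh.write(
                json.dumps(
                    {"sample_id": s.sample_id, "age": s.age, "raw_text": s.raw_text}
                )
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> list[TextSample]:
    samples = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            if obj["sample_id"] in seen:
                raise ValueError(f"duplicate sample_id {obj['sample_id']!r}")
            seen.add(obj["sample_id"])
            samples.append(
                TextSample(
                    sample_id=obj["sample_id"],
                    age=int(obj["age"]),
                    raw_text=obj["raw_text"],
                    sentences=split_sentences(obj["raw_text"]),
                )
            )
    return samples


def write_sentences_jsonl(samples: Iterable[TextSample], path: str | Path) -> None:
    """Export the filtered sentences of every sample."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in samples:
            for sent in filter_sentences(s.sentences):
                fh.write(
                    json.dumps(
                        {
                            "sample_id": s.sample_id,
                            "age": s.age,
                            "position_index": sent.position_index,
                            "text": sent.text,
                        }
                    )
                    + "\n"
                )
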