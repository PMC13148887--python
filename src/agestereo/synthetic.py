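"""Age-conditioned synthetic corpus generator with planted stereotype structure.

A real audit corpus (LLM responses to a neutral age-description prompt) is
not distributable, so every pipeline stage is exercised against
synthetic corpora whose statistical structure is known by construction:

* each age has an :class:`AgeProfile` giving per-content-slot sampling
  probabilities for the eight (subdimension, valence) lexicon cells, with the
  remainder of slots filled from a neutral filler vocabulary disjoint from
  the lexicon (so counting oracles are exact);
* responses carry boilerplate opening/closing sentences and, with some
  probability, a colon-terminated list header, to exercise the sentence
  filters realistically;
* the planted per-age profiles follow the qualitative result structure of
  age-stereotype audits: warmth rising to a mid-life peak then declining
  gently while remaining higher for older than for younger ages, competence
  peaking at 30 and declining steadily from 60, and the positive
  assertiveness rate strictly decreasing with age.

Content words are allocated per response by expected count with stochastic
rounding (variance control), so planted rate differences between ages are
recoverable at the study's sample size of 100 responses per age.  Ground
truth (the sampled cell of every planted word, per sentence) is emitted
alongside the text, never embedded in it.

The generator targets statistical structure only; it makes no attempt to
imitate LLM fluency or grammar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import TextSample, split_sentences, word_count
from .lexicon import CELLS, ScmLexicon
from .wordcount import SubdimensionCountTable

__all__ = [
    "AgeProfile",
    "GeneratorConfig",
    "SentenceGroundTruth",
    "default_profiles",
    "three_regime_profiles",
    "generate_corpus",
    "ground_truth_counts",
    "SyntheticProvider",
    "DEFAULT_OPENERS",
    "DEFAULT_CLOSERS",
    "DEFAULT_LIST_HEADERS",
    "FILLER_WORDS",
]

#: Neutral filler vocabulary; must stay disjoint from any lexicon in use.
FILLER_WORDS: tuple[str, ...] = (
    "routine", "schedule", "hobby", "garden", "book", "music", "weather",
    "kitchen", "window", "street", "coffee", "morning", "afternoon",
    "neighbor", "memory", "lesson", "project", "task", "detail", "habit",
    "balance", "moment", "season", "corner", "table", "letter", "photo",
    "travel", "recipe", "puzzle", "journey", "story", "path", "view",
)

DEFAULT_OPENERS: tuple[str, ...] = (
    "It's important to note that personality can vary widely among individuals, regardless of age.",
    "Keep in mind that every person is unique and these are only broad tendencies.",
    "Of course, no two people of the same age are exactly alike.",
    "Personality is shaped by many factors, and age is only one of them.",
)

DEFAULT_CLOSERS: tuple[str, ...] = (
    "I hope this gives you a useful overview.",
    "Ultimately, individual personality depends on much more than age alone.",
    "These are broad tendencies rather than fixed rules.",
    "Remember that individual differences matter more than any age pattern.",
)

DEFAULT_LIST_HEADERS: tuple[str, ...] = (
    "Here are some common characteristics:",
    "Typical traits include the following:",
    "Some general patterns are:",
)


@dataclass(frozen=True)
class AgeProfile:
    """Planted content structure for one age."""

    age: int
    subdim_rates: dict[tuple[str, int], float]
    warmth_level: float
    competence_level: float
    sentences_per_response: tuple[int, int] = (5, 8)
    words_per_sentence: tuple[int, int] = (5, 8)  # content slots per body sentence

    def __post_init__(self) -> None:
        rates = {cell: float(self.subdim_rates.get(cell, 0.0)) for cell in CELLS}
        object.__setattr__(self, "subdim_rates", rates)
        if any(p < 0 or p > 1 for p in rates.values()):
            raise ValueError("subdim_rates must lie in [0, 1]")
        if sum(rates.values()) > 1 + 1e-12:
            raise ValueError("subdim_rates must sum to at most 1")
        for name in ("warmth_level", "competence_level"):
            v = getattr(self, name)
            if not (-1 <= v <= 1):
                raise ValueError(f"{name} must lie in [-1, 1]")
        for name in ("sentences_per_response", "words_per_sentence"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} range {lo}..{hi} is empty or invalid")


@dataclass(frozen=True)
class GeneratorConfig:
    profiles: tuple[AgeProfile, ...]
    responses_per_age: int = 100
    seed: int = 0
    openers: tuple[str, ...] = DEFAULT_OPENERS
    closers: tuple[str, ...] = DEFAULT_CLOSERS
    list_headers: tuple[str, ...] = DEFAULT_LIST_HEADERS
    list_header_probability: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        ages = [p.age for p in self.profiles]
        if len(ages) != len(set(ages)):
            raise ValueError("one profile per age required")
        if self.responses_per_age < 1:
            raise ValueError("responses_per_age must be >= 1")
        if not (0 <= self.list_header_probability <= 1):
            raise ValueError("list_header_probability must lie in [0, 1]")
        if not self.openers or not self.closers or not self.list_headers:
            raise ValueError("boilerplate pools must be non-empty")


@dataclass(frozen=True)
class SentenceGroundTruth:
    """Planted draws of one body sentence (empty draws list = filler only)."""

    sample_id: str
    age: int
    position_index: int
    word_count: int
    draws: tuple[tuple[str, int, str], ...]  # (subdimension, valence, word)


# Planted per-age levels.  All nine values of each dimension are pairwise
# distinct with gaps of 0.12, so the rank order of per-age means is
# statistically identifiable at 100 responses per age.
_WARMTH_LEVELS = {
    10: -0.06, 20: 0.06, 30: 0.18, 40: 0.90, 50: 0.78,
    60: 0.66, 70: 0.54, 80: 0.42, 90: 0.30,
}
_COMPETENCE_LEVELS = {
    10: 0.18, 20: 0.42, 30: 0.90, 40: 0.78, 50: 0.66,
    60: 0.54, 70: 0.30, 80: 0.06, 90: -0.06,
}
_WARMTH_RATE_TOTAL = 0.20  # per-slot probability mass on warmth cells
_ASSERT_POS_RATES = {age: 0.045 - 0.005 * i for i, age in enumerate(range(10, 100, 10))}
_NEG_BASE = 0.01  # baseline rate for ability-/assertiveness-negative cells


def _profile_rates(age: int) -> dict[tuple[str, int], float]:
    wl = _WARMTH_LEVELS[age]
    cl = _COMPETENCE_LEVELS[age]
    p_as_pos = _ASSERT_POS_RATES[age]
    # ability+ is set so the net competence signal per slot is affine in the
    # planted competence level: net = 0.035 + 0.10 * cl
    p_ab_pos = (0.035 + 0.10 * cl) + 2 * _NEG_BASE - p_as_pos
    q = _WARMTH_RATE_TOTAL / 4.0
    return {
        ("sociability", +1): q * (1 + wl),
        ("sociability", -1): q * (1 - wl),
        ("morality", +1): q * (1 + wl),
        ("morality", -1): q * (1 - wl),
        ("ability", +1): p_ab_pos,
        ("ability", -1): _NEG_BASE,
        ("assertiveness", +1): p_as_pos,
        ("assertiveness", -1): _NEG_BASE,
    }


def default_profiles() -> list[AgeProfile]:
    """Nine profiles (ages 10..90) with the planted study structure."""
    return [
        AgeProfile(
            age=age,
            subdim_rates=_profile_rates(age),
            warmth_level=_WARMTH_LEVELS[age],
            competence_level=_COMPETENCE_LEVELS[age],
        )
        for age in range(10, 100, 10)
    ]


def three_regime_profiles() -> list[AgeProfile]:
    """Profiles with three sharply separated vocabulary regimes.

    Young ages (10, 20) lean on assertiveness vocabulary, middle ages
    (30-50) on ability vocabulary, old ages (60-90) on sociability/morality
    vocabulary — a block structure that the similarity analysis should
    recover as three clusters.
    """
    regimes = {
        (10, 20): {("assertiveness", +1): 0.30, ("assertiveness", -1): 0.02},
        (30, 40, 50): {("ability", +1): 0.30, ("ability", -1): 0.02},
        (60, 70, 80, 90): {("sociability", +1): 0.16, ("morality", +1): 0.16},
    }
    profiles = []
    for ages, rates in regimes.items():
        for age in ages:
            profiles.append(
                AgeProfile(
                    age=age,
                    subdim_rates=rates,
                    warmth_level=0.5 if ("sociability", +1) in rates else 0.0,
                    competence_level=0.5 if ("ability", +1) in rates else 0.0,
                )
            )
    return sorted(profiles, key=lambda p: p.age)


def _check_filler_disjoint(lexicon: ScmLexicon) -> None:
    clash = set(FILLER_WORDS) & set(lexicon.words())
    if clash:
        raise ValueError(f"filler vocabulary overlaps the lexicon: {sorted(clash)}")


def _join_words(words: list[str]) -> str:
    if len(words) == 1:
        return words[0]
    return ", ".join(words[:-1]) + " and " + words[-1]


def _generate_response(
    profile: AgeProfile,
    config: GeneratorConfig,
    lexicon: ScmLexicon,
    rng: np.random.Generator,
    sample_id: str,
) -> tuple[str, list[SentenceGroundTruth]]:
    lo, hi = profile.sentences_per_response
    n_body = int(rng.integers(lo, hi + 1))
    wlo, whi = profile.words_per_sentence
    slots = [int(rng.integers(wlo, whi + 1)) for _ in range(n_body)]
    total_slots = sum(slots)

    # expected count per cell with stochastic rounding (variance control)
    items: list[tuple[str, tuple[str, int] | None]] = []
    for cell in CELLS:
        expect = profile.subdim_rates[cell] * total_slots
        count = int(np.floor(expect))
        if rng.random() < expect - count:
            count += 1
        pool = lexicon.cell_words(*cell)
        if not pool and count > 0:
            raise ValueError(f"lexicon has no words for cell {cell}")
        for _ in range(count):
            items.append((pool[int(rng.integers(len(pool)))], cell))
    if len(items) > total_slots:  # only reachable with extreme rates
        rng.shuffle(items)
        items = items[:total_slots]
    while len(items) < total_slots:
        items.append((FILLER_WORDS[int(rng.integers(len(FILLER_WORDS)))], None))
    rng.shuffle(items)

    # assemble sentences
    body: list[tuple[str, tuple[tuple[str, int, str], ...]]] = []
    cursor = 0
    for n in slots:
        chunk = items[cursor : cursor + n]
        cursor += n
        words = [w for w, _ in chunk]
        draws = tuple(
            (cell[0], cell[1], w) for w, cell in chunk if cell is not None
        )
        body.append((f"They are often {_join_words(words)}.", draws))

    header_at = (
        int(rng.integers(n_body))
        if rng.random() < config.list_header_probability
        else None
    )
    header = config.list_headers[int(rng.integers(len(config.list_headers)))]
    opener = config.openers[int(rng.integers(len(config.openers)))]
    closer = config.closers[int(rng.integers(len(config.closers)))]

    parts: list[tuple[str, bool]] = [(opener, False)]  # (text, is_header)
    for i, (text, _) in enumerate(body):
        if header_at is not None and i == header_at:
            parts.append((header, True))
        parts.append((text, False))
    parts.append((closer, False))

    raw = "".join(t + ("\n" if is_hdr else " ") for t, is_hdr in parts).strip()

    # ground truth references body sentences by their position in the split
    records = []
    pos_of_body: list[int] = []
    pos = 0
    for t, is_hdr in parts:
        if not is_hdr and t not in (opener, closer):
            pos_of_body.append(pos)
        pos += 1
    for (text, draws), position in zip(body, pos_of_body):
        records.append(
            SentenceGroundTruth(
                sample_id=sample_id,
                age=profile.age,
                position_index=position,
                word_count=word_count(text),
                draws=draws,
            )
        )
    return raw, records


def generate_corpus(
    config: GeneratorConfig, lexicon: ScmLexicon
) -> tuple[list[TextSample], list[SentenceGroundTruth]]:
    """Generate ``responses_per_age`` samples per profile, with ground truth.

    Deterministic under ``config.seed``: the generator for each response is
    seeded by ``(seed, age, replicate)``, so corpora are byte-identical
    across runs and independent of generation order.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    _check_filler_disjoint(lexicon)
    samples: list[TextSample] = []
    truth: list[SentenceGroundTruth] = []
    for profile in config.profiles:
        for rep in range(config.responses_per_age):
            rng = np.random.default_rng([config.seed, profile.age, rep])
            sid = f"age{profile.age:02d}_r{rep:03d}"
            raw, records = _generate_response(profile, config, lexicon, rng, sid)
            samples.append(
                TextSample(
                    sample_id=sid,
                    age=profile.age,
                    raw_text=raw,
                    sentences=split_sentences(raw),
                )
            )
            truth.extend(records)
    return samples, truth


def ground_truth_counts(
    truth: list[SentenceGroundTruth],
    lexicon: ScmLexicon,
    ages: list[int] | None = None,
) -> SubdimensionCountTable:
    """Exact per-age tally of planted draws, resolved through the lexicon.

    Each drawn word increments *every* lexicon cell it belongs to (matching
    the multi-category counting rule of the pipeline), and the total word
    count is the token total of the generator's body sentences — the
    sentences that survive preprocessing by construction.  This is the
    oracle for the word-count stage and is computed purely from generator
    records, independent of the preprocessing and counting code paths.
    """
    if ages is None:
        ages = sorted({r.age for r in truth})
    totals = {age: 0 for age in ages}
    counts = {age: {cell: 0 for cell in CELLS} for age in ages}
    for r in truth:
        if r.age not in totals:
            raise ValueError(f"record for unexpected age {r.age}")
        totals[r.age] += r.word_count
        for _sub, _val, word in r.draws:
            for entry in lexicon.lookup(word):
                counts[r.age][(entry.subdimension, entry.valence)] += 1
    return SubdimensionCountTable(
        ages=list(ages), total_word_count=totals, counts=counts
    )


def write_ground_truth_jsonl(
    truth: list[SentenceGroundTruth], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in truth:
            fh.write(
                json.dumps(
                    {
                        "sample_id": r.sample_id,
                        "age": r.age,
                        "position_index": r.position_index,
                        "word_count": r.word_count,
                        "draws": [list(d) for d in r.draws],
                    }
                )
                + "\n"
            )


class SyntheticProvider:
    """Adapter exposing the generator through the text-provider interface.

    Parses the prompted age out of the prompt and serves successive
    replicates for that age; deterministic given the config seed.
    """

    def __init__(self, config: GeneratorConfig, lexicon: ScmLexicon):
        _check_filler_disjoint(lexicon)
        self.config = config
        self.lexicon = lexicon
        self._profiles = {p.age: p for p in config.profiles}
        self._counters: dict[int, int] = {}

    def generate(
        self, prompt: str, temperature: float, top_p: float, max_tokens: int
    ) -> str:
        import re

        m = re.search(r"(\d+)", prompt)
        if not m:
            raise ValueError(f"no age found in prompt {prompt!r}")
        age = int(m.group(1))
        if age not in self._profiles:
            raise ValueError(f"no profile for age {age}")
        rep = self._counters.get(age, 0)
        self._counters[age] = rep + 1
        rng = np.random.default_rng([self.config.seed, age, rep])
        raw, _ = _generate_response(
            self._profiles[age], self.config, self.lexicon,
            rng, f"age{age:02d}_r{rep:03d}",
        )
        return raw

    def identifier(self) -> str:
        return f"synthetic-provider(seed={self.config.seed})"
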