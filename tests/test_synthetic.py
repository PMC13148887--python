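"""Synthetic corpus generator: planted structure, determinism, oracles."""

import numpy as np
import pytest

from agestereo.corpus import CollectionConfig, collect_corpus, filter_sentences
from agestereo.lexicon import CELLS, builtin_lexicon
from agestereo.synthetic import (
    FILLER_WORDS,
    AgeProfile,
    GeneratorConfig,
    SyntheticProvider,
    default_profiles,
    generate_corpus,
    ground_truth_counts,
    three_regime_profiles,
)


class TestDefaultProfiles:
    profiles = {p.age: p for p in default_profiles()}

    def test_nine_ages_covered_exactly(self):
        assert sorted(self.profiles) == list(range(10, 100, 10))

    def test_all_probabilities_valid(self):
        for p in self.profiles.values():
            assert all(0 <= v <= 1 for v in p.subdim_rates.values())
            assert sum(p.subdim_rates.values()) <= 1

    def test_positive_assertiveness_declines_with_age(self):
        rates = [self.profiles[a].subdim_rates[("assertiveness", +1)] for a in sorted(self.profiles)]
        assert rates[-1] < rates[0]
        assert all(b < a for a, b in zip(rates, rates[1:]))  # strictly decreasing

    def test_warmth_rises_to_midlife_peak_then_declines(self):
        wl = {a: p.warmth_level for a, p in self.profiles.items()}
        assert wl[10] < wl[20] < wl[30] < wl[40]
        assert wl[40] > wl[50] > wl[60] > wl[70] > wl[80] > wl[90]
        # older adults remain warmer than the youngest groups
        assert min(wl[60], wl[70], wl[80], wl[90]) > max(wl[10], wl[20], wl[30])

    def test_competence_peaks_at_thirty_and_declines_from_sixty(self):
        cl = {a: p.competence_level for a, p in self.profiles.items()}
        assert max(cl, key=cl.get) == 30
        assert cl[60] > cl[70] > cl[80] > cl[90]

    def test_levels_are_pairwise_distinct(self):
        for attr in ("warmth_level", "competence_level"):
            values = [getattr(p, attr) for p in self.profiles.values()]
            assert len(set(values)) == len(values)


class TestProfileValidation:
    def test_rates_must_sum_to_at_most_one(self):
        with pytest.raises(ValueError, match="at most 1"):
            AgeProfile(age=10, subdim_rates={c: 0.2 for c in CELLS},
                       warmth_level=0.0, competence_level=0.0)

    def test_empty_sentence_range_rejected(self):
        with pytest.raises(ValueError):
            AgeProfile(age=10, subdim_rates={}, warmth_level=0.0,
                       competence_level=0.0, sentences_per_response=(5, 3))


class TestGenerateCorpus:
    def test_sample_count(self, lexicon):
        cfg = GeneratorConfig(profiles=tuple(default_profiles()), responses_per_age=3, seed=0)
        samples, truth = generate_corpus(cfg, lexicon)
        assert len(samples) == 27
        assert len({s.sample_id for s in samples}) == 27

    def test_same_seed_gives_byte_identical_corpora(self, lexicon):
        cfg = GeneratorConfig(profiles=tuple(default_profiles()), responses_per_age=2, seed=5)
        s1, t1 = generate_corpus(cfg, lexicon)
        s2, t2 = generate_corpus(cfg, lexicon)
        assert [s.raw_text for s in s1] == [s.raw_text for s in s2]
        assert t1 == t2

    def test_different_seed_differs(self, lexicon):
        p = tuple(default_profiles())
        s1, _ = generate_corpus(GeneratorConfig(profiles=p, responses_per_age=2, seed=5), lexicon)
        s2, _ = generate_corpus(GeneratorConfig(profiles=p, responses_per_age=2, seed=6), lexicon)
        assert [s.raw_text for s in s1] != [s.raw_text for s in s2]

    def test_forced_list_headers_are_filtered_out(self, lexicon):
        cfg = GeneratorConfig(
            profiles=tuple(default_profiles()), responses_per_age=2, seed=1,
            list_header_probability=1.0,
        )
        samples, _ = generate_corpus(cfg, lexicon)
        for s in samples:
            assert any(sent.ends_with_colon for sent in s.sentences)
            assert not any(sent.ends_with_colon for sent in filter_sentences(s.sentences))

    def test_ground_truth_positions_point_at_body_sentences(self, small_corpus, lexicon):
        samples, truth = small_corpus
        by_id = {s.sample_id: s for s in samples}
        for rec in truth[:200]:
            sent = by_id[rec.sample_id].sentences[rec.position_index]
            assert not sent.is_first and not sent.is_last
            assert not sent.ends_with_colon
            assert sent.word_count == rec.word_count
            toks = set(sent.text.lower().replace(",", " ").replace(".", " ").split())
            for _, _, word in rec.draws:
                assert word in toks

    def test_body_sentences_survive_filtering(self, small_corpus):
        samples, truth = small_corpus
        by_id = {s.sample_id: s for s in samples}
        n_body = {}
        for rec in truth:
            n_body[rec.sample_id] = n_body.get(rec.sample_id, 0) + 1
        for s in samples:
            assert len(filter_sentences(s.sentences)) == n_body[s.sample_id]

    def test_overlapping_filler_rejected(self):
        from agestereo.lexicon import DIMENSION_OF, LexiconEntry, ScmLexicon

        clash = ScmLexicon(
            [LexiconEntry(word=FILLER_WORDS[0], dimension="warmth",
                          subdimension="sociability", valence=1),
             LexiconEntry(word="wise", dimension="competence",
                          subdimension="ability", valence=1)]
        )
        cfg = GeneratorConfig(profiles=tuple(default_profiles()), responses_per_age=1)
        with pytest.raises(ValueError, match="overlaps"):
            generate_corpus(cfg, clash)


class TestGroundTruthCounts:
    def test_empty_corpus_gives_all_zero_table(self, lexicon):
        table = ground_truth_counts([], lexicon, ages=[10, 20])
        assert table.total_word_count == {10: 0, 20: 0}
        assert all(c == 0 for age in (10, 20) for c in table.counts[age].values())

    def test_zero_rate_cell_stays_zero(self, lexicon):
        # three-regime profiles leave several cells at rate zero
        cfg = GeneratorConfig(profiles=tuple(three_regime_profiles()),
                              responses_per_age=5, seed=2)
        _, truth = generate_corpus(cfg, lexicon)
        table = ground_truth_counts(truth, lexicon)
        assert table.cell(10, "ability", +1) == 0
        assert table.cell(60, "assertiveness", +1) == 0
        assert table.cell(10, "assertiveness", +1) > 0

    def test_oracle_equals_pipeline_counts_exactly(self, small_corpus, lexicon):
        from agestereo.wordcount import (
            count_subdimensions,
            exclude_cross_age_common,
            extract_content_words,
            zipf_common_terms,
        )

        samples, truth = small_corpus
        lemmas, totals = {}, {}
        for s in samples:
            for sent in filter_sentences(s.sentences):
                lemmas.setdefault(s.age, []).extend(extract_content_words(sent.text))
                totals[s.age] = totals.get(s.age, 0) + sent.word_count
        common = zipf_common_terms(lemmas, top_fraction=1.0)
        retained, _ = exclude_cross_age_common(common, max_ages=len(common))
        pipeline = count_subdimensions(lemmas, retained, lexicon, totals)
        oracle = ground_truth_counts(truth, lexicon)
        assert pipeline.to_dataframe().equals(oracle.to_dataframe())


class TestSyntheticProvider:
    def test_provider_matches_generator(self, lexicon):
        cfg = GeneratorConfig(profiles=tuple(default_profiles()), responses_per_age=2, seed=9)
        direct, _ = generate_corpus(cfg, lexicon)
        provider = SyntheticProvider(cfg, lexicon)
        collected = collect_corpus(
            provider,
            CollectionConfig(ages=tuple(range(10, 100, 10)), responses_per_age=2, seed=9),
        )
        assert [s.raw_text for s in collected] == [s.raw_text for s in direct]

    def test_single_request(self, lexicon):
        cfg = GeneratorConfig(profiles=tuple(default_profiles()), responses_per_age=1, seed=0)
        provider = SyntheticProvider(cfg, lexicon)
        samples = collect_corpus(
            provider, CollectionConfig(ages=(10,), responses_per_age=1)
        )
        assert len(samples) == 1 and samples[0].age == 10
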