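"""Template construction, PLS scoring, and per-age summaries."""

import numpy as np
import pytest

from agestereo.embeddings import SyntheticBackend, SyntheticEmbeddingSpec, embed
from agestereo.lexicon import DIMENSION_OF, LexiconEntry, ScmLexicon
from agestereo.scoring import (
    PAIR_TEMPLATE,
    SINGLE_TEMPLATE,
    ScmScorePair,
    build_template_sentences,
    fit_scm_model,
    score_sentences,
    summarize_scores_by_age,
)


def _lex(cells):
    """cells: {(subdimension, valence): [words]}"""
    return ScmLexicon(
        [
            LexiconEntry(word=w, dimension=DIMENSION_OF[sub], subdimension=sub, valence=v)
            for (sub, v), words in cells.items()
            for w in words
        ]
    )


@pytest.fixture(scope="module")
def clean_lexicon(lexicon):
    """Builtin lexicon without polysemous words (one entry per word).

    A word listed under conflicting valences of the same dimension ("play")
    has no single expected score, so exactness checks use this subset.
    """
    multi = {w for w in lexicon.words() if len(lexicon.lookup(w)) > 1}
    return ScmLexicon([e for e in lexicon if e.word not in multi])


@pytest.fixture(scope="module")
def clean_backend(clean_lexicon):
    return SyntheticBackend(SyntheticEmbeddingSpec(noise_sd=0.0, seed=0), clean_lexicon)


class TestBuildTemplates:
    def test_single_adjective_label_rule(self, lexicon):
        sents = build_template_sentences(lexicon, pair_budget=0)
        by_adj = {(s.adjectives, s.warmth_label, s.competence_label) for s in sents}
        assert (("warm",), 1.0, 0.0) in by_adj
        assert (("cold",), -1.0, 0.0) in by_adj
        assert (("timid",), 0.0, -1.0) in by_adj
        assert (("wise",), 0.0, 1.0) in by_adj

    def test_single_template_text(self, lexicon):
        sents = build_template_sentences(lexicon, pair_budget=0)
        assert SINGLE_TEMPLATE.format(adj="warm") in {s.text for s in sents}

    def test_pair_label_is_mean_of_same_class_contributions(self, lexicon):
        sents = build_template_sentences(lexicon, pair_budget=10_000, seed=0)
        pairs = [s for s in sents if len(s.adjectives) == 2]
        assert pairs, "no pair sentences generated"
        for s in pairs:
            # same-class pair: the mean of two identical contributions
            assert abs(s.warmth_label) + abs(s.competence_label) == 1.0
            assert s.text == PAIR_TEMPLATE.format(adj1=s.adjectives[0], adj2=s.adjectives[1])

    def test_three_warmth_positive_adjectives_give_three_pairs(self):
        lex = _lex(
            {
                ("sociability", +1): ["warm", "friendly", "kindly"],
                ("ability", +1): ["wise"],
            }
        )
        sents = build_template_sentences(lex, pair_budget=10)
        pairs = [s for s in sents if len(s.adjectives) == 2]
        assert len(pairs) == 3  # 3 choose 2; the lone competence word pairs with nobody

    def test_pair_budget_caps_sampling_without_replacement(self, lexicon):
        sents = build_template_sentences(lexicon, pair_budget=7, seed=3)
        pairs = [tuple(s.adjectives) for s in sents if len(s.adjectives) == 2]
        assert len(pairs) == 7 == len(set(pairs))

    def test_pair_sampling_is_seeded(self, lexicon):
        a = build_template_sentences(lexicon, pair_budget=5, seed=1)
        b = build_template_sentences(lexicon, pair_budget=5, seed=1)
        c = build_template_sentences(lexicon, pair_budget=5, seed=2)
        assert [s.text for s in a] == [s.text for s in b]
        assert [s.text for s in a] != [s.text for s in c]

    def test_one_sided_lexicon_rejected(self):
        lex = _lex({("sociability", +1): ["warm"]})
        with pytest.raises(ValueError, match="competence"):
            build_template_sentences(lex)


def _fit(lexicon, backend, pair_budget=0, n_components=8):
    templates = build_template_sentences(lexicon, pair_budget=pair_budget, seed=0)
    emb = embed(backend, [t.text for t in templates])
    labels = np.array([[t.warmth_label, t.competence_label] for t in templates])
    return templates, emb, labels, fit_scm_model(emb, labels, n_components=n_components)


class TestFitAndScore:
    def test_exact_recovery_on_noiseless_separable_embeddings(self, clean_lexicon, clean_backend):
        # ordinary least squares is exact on this geometry; PLS must match
        templates, emb, labels, model = _fit(clean_lexicon, clean_backend)
        assert np.allclose(model.predict(emb.vectors), labels, atol=1e-6)

    def test_training_sentence_rescored_to_its_label(self, clean_lexicon, clean_backend):
        templates, emb, labels, model = _fit(clean_lexicon, clean_backend)
        scores = score_sentences(model, emb)
        idx = next(i for i, t in enumerate(templates) if t.adjectives == ("warm",))
        assert scores[idx].warmth == pytest.approx(1.0, abs=1e-6)
        assert scores[idx].competence == pytest.approx(0.0, abs=1e-6)

    def test_held_out_warm_adjective_scores_positive_warmth(self, clean_lexicon, clean_backend):
        # drop "affectionate" from training; its embedding still lies on the
        # sociability axis, so predicted warmth must be positive
        held_out = "affectionate"
        reduced = ScmLexicon([e for e in clean_lexicon if e.word != held_out])
        _, _, _, model = _fit(reduced, clean_backend, pair_budget=60)
        probe = embed(clean_backend, [SINGLE_TEMPLATE.format(adj=held_out)])
        (score,) = score_sentences(model, probe)
        assert score.warmth > 0

    def test_identical_labels_rejected(self, clean_lexicon, clean_backend):
        templates = build_template_sentences(clean_lexicon, pair_budget=0)
        emb = embed(clean_backend, [t.text for t in templates])
        with pytest.raises(ValueError, match="positive and negative"):
            fit_scm_model(emb, np.ones((emb.n, 2)), n_components=2)

    def test_too_many_components_rejected(self, clean_lexicon, clean_backend):
        templates, emb, labels, _ = _fit(clean_lexicon, clean_backend)
        with pytest.raises(ValueError, match="fewer components"):
            fit_scm_model(emb, labels, n_components=emb.n + 5)

    def test_effective_components_clamped_to_rank(self, clean_lexicon, clean_backend):
        _, _, _, model = _fit(clean_lexicon, clean_backend, n_components=25)
        assert model.n_components == model.meta["train_rank"] <= 4

    def test_dimension_mismatch_names_both_dims(self, clean_lexicon, clean_backend):
        _, _, _, model = _fit(clean_lexicon, clean_backend)
        other = SyntheticBackend(SyntheticEmbeddingSpec(dim=16), clean_lexicon)
        probe = embed(other, ["warm and wise people here"])
        with pytest.raises(ValueError, match="16.*64|64.*16"):
            score_sentences(model, probe)

    def test_zero_vector_prediction_equals_intercept(self, clean_lexicon, clean_backend):
        _, emb, labels, model = _fit(clean_lexicon, clean_backend)
        coef = model.pls.coef_  # (2, dim); intercept computed independently
        intercept = labels.mean(axis=0) - emb.vectors.mean(axis=0) @ coef.T
        pred = model.predict(np.zeros((1, emb.dim)))[0]
        assert np.allclose(pred, np.clip(intercept, -1, 1), atol=1e-8)

    def test_scores_clipped_to_unit_interval(self, clean_lexicon, clean_backend):
        _, emb, labels, model = _fit(clean_lexicon, clean_backend)
        big = embed(clean_backend, ["warm warm warm warm people"])
        (score,) = score_sentences(model, big)
        assert score.warmth == 1.0
        assert model.meta["last_clip_rate"] > 0

    def test_sign_calibration_on_held_out_singles(self, lexicon, noise_free_backend):
        # only adjectives with an unambiguous (dimension, valence) label have
        # a well-defined expected sign
        unambiguous = [w for w in lexicon.words() if len(lexicon.lookup(w)) == 1]
        correct = total = 0
        for held_out in unambiguous[:20]:
            reduced = ScmLexicon([e for e in lexicon if e.word != held_out])
            _, _, _, model = _fit(reduced, noise_free_backend, pair_budget=60)
            probe = embed(noise_free_backend, [SINGLE_TEMPLATE.format(adj=held_out)])
            (score,) = score_sentences(model, probe)
            (entry,) = lexicon.lookup(held_out)
            value = score.warmth if entry.dimension == "warmth" else score.competence
            correct += int(np.sign(value) == entry.valence)
            total += 1
        assert correct / total >= 0.95


class TestSummaries:
    def test_singleton_groups_flagged(self):
        scores = [ScmScorePair("a", 0.5, 0.1), ScmScorePair("b", -0.2, 0.3)]
        summary = summarize_scores_by_age(scores, {"a": 10, "b": 20})
        assert summary.table.loc[0, "warmth_mean"] == pytest.approx(0.5)
        assert np.isnan(summary.table.loc[0, "warmth_sd"])
        assert summary.welch["warmth"] is None
        assert "n=1" in summary.welch_errors["warmth"]

    def test_constant_scores_mean_preserved_but_welch_degenerate(self):
        scores = [ScmScorePair(f"s{i}", 0.3, 0.3) for i in range(10)]
        ages = {f"s{i}": 10 + 10 * (i % 2) for i in range(10)}
        summary = summarize_scores_by_age(scores, ages)
        assert np.allclose(summary.table["warmth_mean"], 0.3)
        assert summary.welch["warmth"] is None
        assert "zero variance" in summary.welch_errors["warmth"]

    def test_planted_increasing_warmth_recovered(self):
        rng = np.random.default_rng(0)
        scores, ages = [], {}
        for j, age in enumerate(range(10, 60, 10)):
            for i in range(50):
                sid = f"{age}:{i}"
                scores.append(ScmScorePair(sid, 0.1 * j + rng.normal(0, 0.02), 0.0))
                ages[sid] = age
        summary = summarize_scores_by_age(scores, ages)
        assert np.all(np.diff(summary.table["warmth_mean"].to_numpy()) > 0)

    def test_unmapped_sentence_rejected(self):
        with pytest.raises(ValueError, match="without an age"):
            summarize_scores_by_age([ScmScorePair("a", 0.0, 0.0)], {})
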