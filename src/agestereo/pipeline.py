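"""End-to-end reproducible run: generate/ingest -> preprocess -> embed ->
similarity -> score -> ANOVA -> word counts, with a run manifest.

A single config object (loadable from YAML) governs all stages; defaults
mirror the study design (temperature 1.0, top_p 1.0, 2,048 max tokens,
100 responses per age, ages 10..90).  With the synthetic backend the whole
run is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import corpus as cp
from .embeddings import EmbeddingMatrix, SyntheticBackend, SyntheticEmbeddingSpec, embed
from .lexicon import ScmLexicon, builtin_lexicon, load_lexicon
from .scoring import (
    AgeScoreSummary,
    ScmScorePair,
    build_template_sentences,
    fit_scm_model,
    score_sentences,
    summarize_scores_by_age,
)
from .similarity import AgeSimilarityMatrix, age_similarity, reduce_pca, sample_mean_vectors
from .synthetic import (
    GeneratorConfig,
    SentenceGroundTruth,
    default_profiles,
    generate_corpus,
    write_ground_truth_jsonl,
)
from .wordcount import (
    SubdimensionCountTable,
    VocabularyFilterReport,
    count_subdimensions,
    exclude_cross_age_common,
    extract_content_words,
    zipf_common_terms,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one run."""

    seed: int = 0
    responses_per_age: int = 100
    embedding_dim: int = 64
    embedding_noise_sd: float = 0.05
    embedding_signal_weight: float = 1.0
    pca_components: float | int = 0.9
    pls_components: int = 25
    pair_budget: int = 200
    top_fraction: float = 0.8
    max_common_ages: int = 6
    list_header_probability: float = 0.3
    lexicon_path: str | None = None  # None -> built-in seed lexicon

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    samples: list[cp.TextSample]
    ground_truth: list[SentenceGroundTruth]
    filtered: dict[str, list[cp.Sentence]]  # sample_id -> surviving sentences
    filter_counts: dict[str, int]
    similarity: AgeSimilarityMatrix
    scores: list[ScmScorePair]
    summary: AgeScoreSummary
    count_table: SubdimensionCountTable
    exclusion_report: VocabularyFilterReport
    sentence_embeddings: EmbeddingMatrix
    sentence_to_sample: dict[str, str]
    manifest: dict = field(default_factory=dict)


def _stage_filter(samples: list[cp.TextSample]):
    filtered: dict[str, list[cp.Sentence]] = {}
    totals = {"total": 0, "removed_positional": 0, "removed_short": 0,
              "removed_colon": 0, "kept": 0}
    for s in samples:
        rep = cp.filter_report(s.sentences)
        for k in totals:
            totals[k] += rep[k]
        filtered[s.sample_id] = cp.filter_sentences(s.sentences)
    logger.info("filtering: %s", totals)
    return filtered, totals


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    samples: list[cp.TextSample] | None = None,
    lexicon: ScmLexicon | None = None,
) -> PipelineResult:
    """Execute the full study on a synthetic (or supplied) corpus.

    When ``samples`` is None a synthetic corpus with the default planted
    profiles is generated.  When ``out_dir`` is given, per-stage CSV/JSON
    artifacts and the run manifest are written there.
    """
    t0 = time.time()
    if lexicon is None:
        lexicon = (
            builtin_lexicon()
            if config.lexicon_path is None
            else load_lexicon(config.lexicon_path)
        )

    # stage 1: corpus
    ground_truth: list[SentenceGroundTruth] = []
    if samples is None:
        gen_cfg = GeneratorConfig(
            profiles=tuple(default_profiles()),
            responses_per_age=config.responses_per_age,
            seed=config.seed,
            list_header_probability=config.list_header_probability,
        )
        samples, ground_truth = generate_corpus(gen_cfg, lexicon)

    # stage 2: preprocess
    filtered, filter_counts = _stage_filter(samples)
    sent_ids: list[str] = []
    sent_texts: list[str] = []
    sentence_to_sample: dict[str, str] = {}
    sentence_to_age: dict[str, int] = {}
    sample_to_age = {s.sample_id: s.age for s in samples}
    for s in samples:
        for sent in filtered[s.sample_id]:
            rid = f"{s.sample_id}:{sent.position_index}"
            sent_ids.append(rid)
            sent_texts.append(sent.text)
            sentence_to_sample[rid] = s.sample_id
            sentence_to_age[rid] = s.age

    # stage 3: embed
    backend = SyntheticBackend(
        SyntheticEmbeddingSpec(
            dim=config.embedding_dim,
            signal_weight=config.embedding_signal_weight,
            noise_sd=config.embedding_noise_sd,
            seed=config.seed,
        ),
        lexicon,
    )
    sent_emb = embed(backend, sent_texts, row_ids=sent_ids)

    # stage 4: similarity (PCA on the entire corpus, then sample/group means)
    reduced = reduce_pca(sent_emb, config.pca_components)
    means, sample_ids, dropped = sample_mean_vectors(reduced, sentence_to_sample)
    sim = age_similarity(means, sample_ids, sample_to_age)

    # stage 5: SCM scoring on UNreduced embeddings
    templates = build_template_sentences(
        lexicon, pair_budget=config.pair_budget, seed=config.seed
    )
    tmpl_emb = embed(backend, [t.text for t in templates])
    labels = np.array([[t.warmth_label, t.competence_label] for t in templates])
    model = fit_scm_model(tmpl_emb, labels, n_components=config.pls_components)
    scores = score_sentences(model, sent_emb)
    summary = summarize_scores_by_age(scores, sentence_to_age)

    # stage 6: word counts
    lemmas_by_age: dict[int, list[str]] = {s.age: [] for s in samples}
    totals_by_age: dict[int, int] = {s.age: 0 for s in samples}
    for s in samples:
        for sent in filtered[s.sample_id]:
            lemmas_by_age[s.age].extend(extract_content_words(sent.text))
            totals_by_age[s.age] += sent.word_count
    common = zipf_common_terms(lemmas_by_age, top_fraction=config.top_fraction)
    retained, report = exclude_cross_age_common(common, max_ages=config.max_common_ages)
    table = count_subdimensions(lemmas_by_age, retained, lexicon, totals_by_age)

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "backend": backend.identifier(),
        "n_samples": len(samples),
        "n_sentences_kept": len(sent_ids),
        "dropped_samples": dropped,
        "filter_counts": filter_counts,
        "pls": model.meta | {"train_checksum": model.train_checksum},
        "pca_components": reduced.meta.get("pca_n_components"),
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [],
    }

    result = PipelineResult(
        config=config,
        samples=samples,
        ground_truth=ground_truth,
        filtered=filtered,
        filter_counts=filter_counts,
        similarity=sim,
        scores=scores,
        summary=summary,
        count_table=table,
        exclusion_report=report,
        sentence_embeddings=sent_emb,
        sentence_to_sample=sentence_to_sample,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out_dir / "corpus.jsonl",
        "sentences": out_dir / "sentences.jsonl",
        "similarity": out_dir / "age_similarity.csv",
        "scores": out_dir / "scores.csv",
        "score_summary": out_dir / "score_summary_by_age.csv",
        "welch": out_dir / "welch.json",
        "counts": out_dir / "subdimension_counts.csv",
        "exclusions": out_dir / "excluded_words.csv",
        "manifest": out_dir / "manifest.json",
    }
    cp.write_corpus_jsonl(result.samples, paths["corpus"])
    cp.write_sentences_jsonl(result.samples, paths["sentences"])
    if result.ground_truth:
        paths["ground_truth"] = out_dir / "ground_truth.jsonl"
        write_ground_truth_jsonl(result.ground_truth, paths["ground_truth"])
    result.similarity.to_dataframe().to_csv(paths["similarity"])

    import pandas as pd

    sample_of = result.sentence_to_sample
    age_of = {s.sample_id: s.age for s in result.samples}
    pd.DataFrame(
        {
            "sample_id": [sample_of[sc.sentence_id] for sc in result.scores],
            "age": [age_of[sample_of[sc.sentence_id]] for sc in result.scores],
            "sentence_index": [
                int(sc.sentence_id.rsplit(":", 1)[1]) for sc in result.scores
            ],
            "warmth": [sc.warmth for sc in result.scores],
            "competence": [sc.competence for sc in result.scores],
        }
    ).to_csv(paths["scores"], index=False)
    result.summary.table.to_csv(paths["score_summary"], index=False)
    welch_obj = {
        dim: (asdict(res) if res is not None else {"error": result.summary.welch_errors[dim]})
        for dim, res in result.summary.welch.items()
    }
    with open(paths["welch"], "w", encoding="utf-8") as fh:
        json.dump(welch_obj, fh, indent=2)
    result.count_table.to_dataframe().to_csv(paths["counts"], index=False)
    result.exclusion_report.to_dataframe().to_csv(paths["exclusions"], index=False)

    result.manifest["outputs"] = sorted(str(p) for p in paths.values())
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2)
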