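#!/usr/bin/env python
"""Step 4 — warmth/competence scoring and across-age testing.

Builds labeled template sentences from the stereotype lexicon, fits a PLS
regression from sentence embeddings to (warmth, competence), scores every
corpus sentence on the -1..1 scale, and tests across-age differences with
Welch's heteroscedastic ANOVA.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from agestereo.corpus import filter_sentences, read_corpus_jsonl
from agestereo.embeddings import SyntheticBackend, SyntheticEmbeddingSpec, embed
from agestereo.lexicon import builtin_lexicon
from agestereo.scoring import (
    build_template_sentences,
    fit_scm_model,
    score_sentences,
    summarize_scores_by_age,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--pls-components", type=int, default=25)
parser.add_argument("--pair-budget", type=int, default=200)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

lexicon = builtin_lexicon()
samples = read_corpus_jsonl(args.results / "corpus.jsonl")
backend = SyntheticBackend(
    SyntheticEmbeddingSpec(noise_sd=0.05, seed=args.seed), lexicon
)

templates = build_template_sentences(lexicon, pair_budget=args.pair_budget, seed=args.seed)
train = embed(backend, [t.text for t in templates])
labels = np.array([[t.warmth_label, t.competence_label] for t in templates])
model = fit_scm_model(train, labels, n_components=args.pls_components)
print(f"{len(templates)} template sentences, "
      f"{model.n_components} PLS components (train rank {model.meta['train_rank']})")

ids, texts, to_age = [], [], {}
for s in samples:
    for sent in filter_sentences(s.sentences):
        rid = f"{s.sample_id}:{sent.position_index}"
        ids.append(rid)
        texts.append(sent.text)
        to_age[rid] = s.age
scores = score_sentences(model, embed(backend, texts, row_ids=ids))
summary = summarize_scores_by_age(scores, to_age)

summary.table.to_csv(args.results / "score_summary_by_age.csv", index=False)
pd.DataFrame(
    {"sentence_id": [s.sentence_id for s in scores],
     "age": [to_age[s.sentence_id] for s in scores],
     "warmth": [s.warmth for s in scores],
     "competence": [s.competence for s in scores]}
).to_csv(args.results / "scores.csv", index=False)
with open(args.results / "welch.json", "w") as fh:
    json.dump(
        {d: (asdict(r) if r is not None else {"error": summary.welch_errors[d]})
         for d, r in summary.welch.items()},
        fh, indent=2,
    )

print(summary.table[["age", "n", "warmth_mean", "competence_mean"]].round(3))
peak_w = summary.table.loc[summary.table["warmth_mean"].idxmax()]
peak_c = summary.table.loc[summary.table["competence_mean"].idxmax()]
print(f"warmth peaks at age {peak_w['age']:.0f} (mean {peak_w['warmth_mean']:.3f}); "
      f"competence peaks at age {peak_c['age']:.0f} (mean {peak_c['competence_mean']:.3f})")
for dim, res in summary.welch.items():
    print(f"Welch {dim}: F({res.df1}, {res.df2:.1f}) = {res.F:.2f}, p = {res.p_value:.3g}")
print(f"clip rate {model.meta['last_clip_rate']:.3f}; "
      f"wrote scores.csv, score_summary_by_age.csv, welch.json")
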