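#!/usr/bin/env python
"""Step 3 — text similarity between age groups.

Embeds every surviving sentence, reduces the whole corpus jointly by PCA,
averages vectors per sample and per age, and computes the age-by-age cosine
similarity matrix.  Because PCA centers the corpus, negative similarities
are expected and mark age groups described in opposing terms.
"""

import argparse
from pathlib import Path

import numpy as np

from agestereo.corpus import filter_sentences, read_corpus_jsonl
from agestereo.embeddings import SyntheticBackend, SyntheticEmbeddingSpec, embed
from agestereo.lexicon import builtin_lexicon
from agestereo.similarity import age_similarity, reduce_pca, sample_mean_vectors

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--components", type=float, default=0.9,
                    help="integer count or variance fraction in (0,1)")
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

lexicon = builtin_lexicon()
samples = read_corpus_jsonl(args.results / "corpus.jsonl")
backend = SyntheticBackend(
    SyntheticEmbeddingSpec(noise_sd=0.05, seed=args.seed), lexicon
)

ids, texts, to_sample, to_age = [], [], {}, {}
for s in samples:
    for sent in filter_sentences(s.sentences):
        rid = f"{s.sample_id}:{sent.position_index}"
        ids.append(rid)
        texts.append(sent.text)
        to_sample[rid] = s.sample_id
        to_age[s.sample_id] = s.age

n_components = int(args.components) if args.components >= 1 else args.components
reduced = reduce_pca(embed(backend, texts, row_ids=ids), n_components)
means, sample_ids, dropped = sample_mean_vectors(reduced, to_sample)
sim = age_similarity(means, sample_ids, to_age)
sim.to_dataframe().to_csv(args.results / "age_similarity.csv")

print(f"{len(texts)} sentences -> {reduced.meta['pca_n_components']} components "
      f"({100 * sum(reduced.meta['explained_variance_ratio']):.1f}% variance)")
if dropped:
    print(f"dropped {len(dropped)} samples with no surviving sentences")
print(sim.to_dataframe().round(2))

off = sim.values[~np.eye(len(sim.ages), dtype=bool)]
print(f"off-diagonal similarity range: [{off.min():.2f}, {off.max():.2f}]")
print(f"wrote {args.results / 'age_similarity.csv'}")
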