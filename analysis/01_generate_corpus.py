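#!/usr/bin/env python
"""Step 1 — generate the synthetic age-conditioned corpus.

Emulates the study design (nine prompted ages 10..90, 100 responses per age,
~900 samples) with planted stereotype structure: warmth peaking in mid-life,
competence peaking at 30 and declining from 60, positive assertiveness
strictly declining with age.  Writes the corpus and its ground-truth sidecar
under results/.
"""

import argparse
from pathlib import Path

from agestereo.corpus import write_corpus_jsonl
from agestereo.lexicon import builtin_lexicon
from agestereo.synthetic import (
    GeneratorConfig,
    default_profiles,
    generate_corpus,
    write_ground_truth_jsonl,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--responses-per-age", type=int, default=100)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

lexicon = builtin_lexicon()
config = GeneratorConfig(
    profiles=tuple(default_profiles()),
    responses_per_age=args.responses_per_age,
    seed=args.seed,
)
samples, truth = generate_corpus(config, lexicon)

args.out.mkdir(parents=True, exist_ok=True)
write_corpus_jsonl(samples, args.out / "corpus.jsonl")
write_ground_truth_jsonl(truth, args.out / "ground_truth.jsonl")

ages = sorted({s.age for s in samples})
print(f"generated {len(samples)} samples across ages {ages} (seed={args.seed})")
print(f"planted body sentences: {len(truth)}")
print(f"wrote {args.out / 'corpus.jsonl'} and {args.out / 'ground_truth.jsonl'}")
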