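#!/usr/bin/env python
"""Step 2 — sentence-level preprocessing.

Splits every response into sentences and applies the three filters: drop
the first/last sentence (boilerplate disclaimers), drop sentences of three
words or fewer, drop colon-terminated list headers.  Reports how many
sentences each rule removed and writes the surviving sentences.
"""

import argparse
from pathlib import Path

from agestereo.corpus import filter_report, read_corpus_jsonl, write_sentences_jsonl

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

samples = read_corpus_jsonl(args.results / "corpus.jsonl")
totals = {"total": 0, "removed_positional": 0, "removed_short": 0,
          "removed_colon": 0, "kept": 0}
for s in samples:
    rep = filter_report(s.sentences)
    for k in totals:
        totals[k] += rep[k]

write_sentences_jsonl(samples, args.results / "sentences.jsonl")

print(f"{len(samples)} responses, {totals['total']} sentences")
print(f"  removed as first/last sentence: {totals['removed_positional']}")
print(f"  removed as <= 3 words:          {totals['removed_short']}")
print(f"  removed as colon-ending:        {totals['removed_colon']}")
print(f"  kept for analysis:              {totals['kept']}")
print(f"wrote {args.results / 'sentences.jsonl'}")
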