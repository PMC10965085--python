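"""Corpus stage on a miniature n-gram file.

Builds a small Google-Books-style n-gram TSV, then runs the text pipeline:
lowercase → stopword filter → Snowball stemming → anchor-convention
co-occurrence counting → 3-year sliding windows → vocabulary filtering →
subsampling to a constant per-window co-occurrence budget.
"""

import tempfile
from pathlib import Path

from semdrift import (count_cooccurrences, normalize_tokens,
                      read_ngram_records, subsample_pairs, window_and_filter)
from semdrift.corpus import NgramRecord

lines = []
for year in range(1990, 1996):
    lines += [
        f"the running dogs\t{year}\t{30 + year % 3}\t5",
        f"dogs were running\t{year}\t{25}\t4",
        f"semantic drift happens\t{year}\t{40}\t6",
        f"drift of meaning\t{year}\t{35}\t6",
        f"meaning and drift\t{year}\t{20}\t3",
    ]
path = Path(tempfile.mkdtemp()) / "ngrams.tsv"
path.write_text("\n".join(lines) + "\n")

records, stats = read_ngram_records(path, year_min=1990)
print(f"parsed {len(records)} records ({stats['skipped']} skipped)")

normalized = [NgramRecord(tuple(normalize_tokens(r.tokens)), r.year,
                          r.match_count)
              for r in records if normalize_tokens(r.tokens)]
print("example normalization:", records[0].tokens, "->",
      normalized[0].tokens)

yearly = count_cooccurrences(normalized, context_window=2)
windows, vocab = window_and_filter(yearly, window_width_years=3,
                                   min_count=100)
print(f"{len(windows)} sliding windows, vocabulary = {vocab.lemmas}")

n_c = min(w.total() for w in windows)
sub = [subsample_pairs(w, n_c, seed) for seed, w in enumerate(windows)]
print(f"after subsampling every window holds exactly {n_c} co-occurrence "
      f"tokens: {[w.total() for w in sub]}")
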