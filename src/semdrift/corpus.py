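"""Time-labeled n-gram records → per-window co-occurrence tables.

The raw material is the Google Books Ngram v2 TSV format, one record per
line::

    ngram TAB year TAB match_count TAB volume_count

with the ngram's tokens separated by spaces.  The pipeline lowercases,
removes stopwords, stems (Snowball English), counts directed co-occurrence
pairs per year, merges years into sliding windows, restricts to a vocabulary
of lemmas frequent in *every* window, and subsamples each window to a
constant number N_c of co-occurrence tokens so that the growth of the corpus
over time does not masquerade as semantic change.

Because the n-gram files present overlapping windows of running text, pairs
are emitted only between each record's first token (the anchor) and its
neighbours at distance 1..w, in both directions: each text position anchors
exactly one n-gram, so no co-occurrence is double counted.
"""

from __future__ import annotations

import gzip
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._porter2 import stem

logger = logging.getLogger(__name__)

SUPPORTED_LANGUAGES = ("english",)


@dataclass(frozen=True)
class NgramRecord:
    """One n-gram occurrence record: tokens with a year and a count."""

    tokens: tuple[str, ...]
    year: int
    match_count: int
    volume_count: int = 0

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("tokens must be non-empty")
        if self.match_count < 0:
            raise ValueError("match_count must be non-negative")


@dataclass
class YearlyCooccurrence:
    """Directed (center, context) → count table for one calendar year."""

    year: int
    counts: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class WindowedCooccurrence:
    """Directed pair counts summed over a sliding window of years."""

    window_start_year: int
    window_width_years: int
    counts: Counter = field(default_factory=Counter)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_arrays(self, vocab: "Vocabulary"):
        """Return (centers, contexts, counts) index arrays over ``vocab``."""
        n = len(self.counts)
        centers = np.empty(n, dtype=np.int64)
        contexts = np.empty(n, dtype=np.int64)
        counts = np.empty(n, dtype=np.int64)
        for k, ((c, x), v) in enumerate(sorted(self.counts.items())):
            centers[k] = vocab.index[c]
            contexts[k] = vocab.index[x]
            counts[k] = v
        return centers, contexts, counts


@dataclass(frozen=True)
class Vocabulary:
    """Deterministically (lexicographically) ordered lemma set."""

    lemmas: tuple[str, ...]

    @property
    def index(self) -> dict[str, int]:
        if not hasattr(self, "_index"):
            object.__setattr__(self, "_index",
                               {w: i for i, w in enumerate(self.lemmas)})
        return self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.lemmas)


def iter_ngram_records(path, year_min: int = 0,
                       stats: Counter | None = None) -> Iterator[NgramRecord]:
    """Stream records from a Google Ngram v2 TSV file (plain or gzip).

    Malformed lines are skipped and counted under ``stats['skipped']``;
    records before ``year_min`` are dropped and counted under
    ``stats['before_year_min']``.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                if stats is not None:
                    stats["skipped"] += 1
                logger.warning("skipping malformed line: %r", line[:80])
                continue
            ngram, year_s, match_s, volume_s = parts
            tokens = tuple(t for t in ngram.split(" ") if t)
            try:
                year, match, volume = int(year_s), int(match_s), int(volume_s)
            except ValueError:
                if stats is not None:
                    stats["skipped"] += 1
                logger.warning("skipping non-integer fields: %r", line[:80])
                continue
            if not tokens or match < 0:
                if stats is not None:
                    stats["skipped"] += 1
                continue
            if year < year_min:
                if stats is not None:
                    stats["before_year_min"] += 1
                continue
            yield NgramRecord(tokens, year, match, volume)


def read_ngram_records(path, year_min: int = 0
                       ) -> tuple[list[NgramRecord], Counter]:
    """Read a whole n-gram file; returns (records, stats counter)."""
    stats: Counter = Counter()
    records = list(iter_ngram_records(path, year_min, stats))
    return records, stats


def load_stopwords(language: str) -> frozenset[str]:
    _check_language(language)
    text = (resources.files("semdrift") / "data" / "stopwords"
            / f"{language}.txt").read_text(encoding="utf-8")
    return frozenset(w for w in text.split() if w)


def _check_language(language: str) -> None:
    if language not in SUPPORTED_LANGUAGES:
        raise ValueError(
            f"unsupported language {language!r}; supported: "
            f"{', '.join(SUPPORTED_LANGUAGES)}"
        )


def normalize_tokens(tokens: Sequence[str], language: str = "english",
                     stopwords: frozenset[str] | None = None) -> list[str]:
    """Lowercase, drop stopwords, and stem; order of survivors preserved.

    Stopwords are matched on the lowercased raw token, before stemming, so
    that e.g. "The" is removed but "there" (not in the list) is stemmed.
    """
    _check_language(language)
    if stopwords is None:
        stopwords = load_stopwords(language)
    out = []
    for tok in tokens:
        low = tok.lower()
        if low in stopwords:
            continue
        out.append(stem(low))
    return out


def count_cooccurrences(records: Iterable[NgramRecord],
                        context_window: int = 2,
                        ) -> list[YearlyCooccurrence]:
    """Aggregate anchor-convention directed pair counts per year.

    For each record with (already normalized) tokens ``t0 t1 ... tk``, pairs
    (t0, td) and (td, t0) for d = 1..context_window are each credited with
    the record's match_count.  Identical-lemma pairs are kept.  The resulting
    directed table is symmetric by construction.
    """
    by_year: dict[int, YearlyCooccurrence] = {}
    for rec in records:
        toks = rec.tokens
        if len(toks) < 2:
            continue
        table = by_year.get(rec.year)
        if table is None:
            table = by_year[rec.year] = YearlyCooccurrence(rec.year)
        anchor = toks[0]
        for d in range(1, min(context_window, len(toks) - 1) + 1):
            other = toks[d]
            table.counts[(anchor, other)] += rec.match_count
            table.counts[(other, anchor)] += rec.match_count
    return [by_year[y] for y in sorted(by_year)]


def _center_marginal(counts: Counter) -> Counter:
    marg: Counter = Counter()
    for (center, _context), v in counts.items():
        marg[center] += v
    return marg


def window_and_filter(yearly: Sequence[YearlyCooccurrence],
                      window_width_years: int = 10,
                      min_count: int = 100,
                      ) -> tuple[list[WindowedCooccurrence], Vocabulary]:
    """Merge years into stride-1 sliding windows and fix the vocabulary.

    The vocabulary keeps the lemmas whose occurrence count (as pair center)
    is at least ``min_count`` in every window; pairs touching any other
    lemma are removed from every window.
    """
    if not yearly:
        raise ValueError("no yearly co-occurrence data")
    by_year = {t.year: t for t in yearly}
    y0, y1 = min(by_year), max(by_year)
    n_windows = y1 - y0 - window_width_years + 2
    if n_windows < 1:
        raise ValueError(
            f"need at least {window_width_years} consecutive years; "
            f"have {y1 - y0 + 1}"
        )
    windows = []
    for start in range(y0, y0 + n_windows):
        w = WindowedCooccurrence(start, window_width_years)
        for year in range(start, start + window_width_years):
            table = by_year.get(year)
            if table is not None:
                w.counts.update(table.counts)
        windows.append(w)

    survivors: set[str] | None = None
    per_window_counts = []
    for w in windows:
        marg = _center_marginal(w.counts)
        ok = {lemma for lemma, c in marg.items() if c >= min_count}
        per_window_counts.append(len(ok))
        survivors = ok if survivors is None else survivors & ok
    if not survivors:
        raise ValueError(
            "empty vocabulary after frequency filtering; per-window "
            f"survivor counts: {per_window_counts}"
        )
    vocab = Vocabulary(tuple(sorted(survivors)))
    keep = set(vocab.lemmas)
    for w in windows:
        w.counts = Counter({
            pair: v for pair, v in w.counts.items()
            if pair[0] in keep and pair[1] in keep
        })
    return windows, vocab


def subsample_pairs(window: WindowedCooccurrence, n_cooccurrences: int,
                    rng: np.random.Generator | int,
                    ) -> WindowedCooccurrence:
    """Draw exactly N_c co-occurrence tokens without replacement.

    The draw is multivariate hypergeometric over the multiset of pair
    occurrences, so at N_c close to the window total the empirical pair
    distribution is preserved almost exactly.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    pairs = sorted(window.counts.items())
    counts = np.array([v for _, v in pairs], dtype=np.int64)
    total = int(counts.sum())
    if total < n_cooccurrences:
        raise ValueError(
            f"window {window.window_start_year} holds {total} co-occurrence "
            f"tokens < N_c = {n_cooccurrences}; drop the window upstream"
        )
    if total == n_cooccurrences:
        sampled = counts
    else:
        sampled = rng.multivariate_hypergeometric(
            counts, n_cooccurrences, method="marginals")
    out = Counter({pair: int(c) for (pair, _), c in zip(pairs, sampled)
                   if c > 0})
    return WindowedCooccurrence(window.window_start_year,
                                window.window_width_years, out)


def shuffle_time_labels(yearly: Sequence[YearlyCooccurrence],
                        rng: np.random.Generator | int,
                        ) -> list[YearlyCooccurrence]:
    """Reassign the per-year tables to years by a uniform random permutation.

    The multiset of tables is unchanged; only the year → table mapping is
    scrambled.  This is the time-label reshuffling null model: any apparent
    drift that survives it is an artifact of the downstream pipeline.
    """
    if len(yearly) < 2:
        raise ValueError("need at least two years to shuffle")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    years = [t.year for t in yearly]
    perm = rng.permutation(len(yearly))
    return [YearlyCooccurrence(years[i], yearly[perm[i]].counts)
            for i in range(len(yearly))]


# ---------------------------------------------------------------------------
# plain-text persistence

def write_cooccurrence_tsv(window: WindowedCooccurrence, path,
                           seed: int | None = None) -> None:
    """Write "center TAB context TAB count" plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for (c, x), v in sorted(window.counts.items()):
            fh.write(f"{c}\t{x}\t{v}\n")
    meta = {
        "window_start_year": window.window_start_year,
        "window_width_years": window.window_width_years,
        "total_count": window.total(),
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1), encoding="utf-8")


def read_cooccurrence_tsv(path) -> WindowedCooccurrence:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json")
                      .read_text(encoding="utf-8"))
    counts: Counter = Counter()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            c, x, v = line.rstrip("\n").split("\t")
            counts[(c, x)] = int(v)
    return WindowedCooccurrence(meta["window_start_year"],
                                meta["window_width_years"], counts)
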