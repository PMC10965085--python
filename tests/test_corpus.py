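"""Corpus stage: parsing, normalization, counting, windowing, subsampling."""

from collections import Counter

import numpy as np
import pytest

from semdrift import corpus
from semdrift._porter2 import stem
from semdrift.corpus import (NgramRecord, YearlyCooccurrence,
                             count_cooccurrences, normalize_tokens,
                             read_cooccurrence_tsv, read_ngram_records,
                             shuffle_time_labels, subsample_pairs,
                             window_and_filter, write_cooccurrence_tsv)

# hand-traced through the published Porter2 algorithm definition
STEM_CASES = [
    ("running", "run"), ("dogs", "dog"), ("ties", "tie"), ("cries", "cri"),
    ("caresses", "caress"), ("meeting", "meet"), ("agreed", "agre"),
    ("happy", "happi"), ("happiness", "happi"), ("relational", "relat"),
    ("conditional", "condit"), ("rational", "ration"), ("hoping", "hope"),
    ("hopping", "hop"), ("dying", "die"), ("sky", "sky"), ("news", "news"),
    ("generously", "generous"), ("general", "general"),
    ("generate", "generat"), ("semantic", "semant"), ("drift", "drift"),
    ("embedding", "embed"), ("words", "word"), ("argued", "argu"),
    ("arguing", "argu"), ("sensational", "sensat"),
    ("triplicate", "triplic"), ("dependent", "depend"),
    ("adjustment", "adjust"), ("communism", "communism"),
    ("activate", "activ"), ("effective", "effect"), ("bowling", "bowl"),
    ("enjoying", "enjoy"), ("electricity", "electr"), ("falling", "fall"),
    ("knitting", "knit"), ("controlling", "control"), ("roll", "roll"),
    ("exceed", "exceed"), ("inning", "inning"), ("sized", "size"),
    ("cement", "cement"), ("element", "element"),
]


@pytest.mark.parametrize("word,expected", STEM_CASES)
def test_porter2_stems(word, expected):
    assert stem(word) == expected


class TestNormalizeTokens:
    def test_lowercase_stopword_stem(self):
        assert normalize_tokens(["Running", "the", "dogs"]) == ["run", "dog"]

    def test_empty_and_all_stopwords(self):
        assert normalize_tokens([]) == []
        assert normalize_tokens(["the", "of", "and"]) == []

    def test_unsupported_language_lists_supported(self):
        with pytest.raises(ValueError, match="english"):
            normalize_tokens(["mot"], language="french")


class TestNgramReader:
    def test_parse_filter_and_skip(self, tmp_path):
        path = tmp_path / "ngrams.tsv"
        path.write_text(
            "semantic drift\t2000\t5\t3\n"
            "old stuff\t1800\t9\t1\n"
            "bad line without fields\n"
            "word pair\tnot_a_year\t1\t1\n"
            "good pair\t1999\t2\t1\n"
        )
        records, stats = read_ngram_records(path, year_min=1950)
        assert [r.tokens for r in records] == [("semantic", "drift"),
                                               ("good", "pair")]
        assert records[0].year == 2000 and records[0].match_count == 5
        assert stats["skipped"] == 2
        assert stats["before_year_min"] == 1

    def test_gzip_roundtrip(self, tmp_path):
        import gzip
        path = tmp_path / "ngrams.tsv.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("a b\t1990\t4\t2\n")
        records, _ = read_ngram_records(path)
        assert records == [NgramRecord(("a", "b"), 1990, 4, 2)]

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            NgramRecord((), 2000, 1)
        with pytest.raises(ValueError):
            NgramRecord(("a",), 2000, -1)


class TestCountCooccurrences:
    def test_anchor_convention(self):
        recs = [NgramRecord(("a", "b", "c"), 2000, 1)]
        [table] = count_cooccurrences(recs, context_window=2)
        assert table.counts == Counter(
            {("a", "b"): 1, ("a", "c"): 1, ("b", "a"): 1, ("c", "a"): 1})

    def test_match_count_multiplies(self):
        recs = [NgramRecord(("a", "b", "c"), 2000, 7)]
        [table] = count_cooccurrences(recs, context_window=2)
        assert all(v == 7 for v in table.counts.values())

    def test_self_pairs_kept(self):
        recs = [NgramRecord(("a", "a"), 2000, 1)]
        [table] = count_cooccurrences(recs, context_window=2)
        assert table.counts[("a", "a")] == 2  # both directions coincide

    def test_directed_table_symmetric(self, rng):
        words = list("abcdef")
        recs = [NgramRecord(tuple(rng.choice(words, size=3)), 2001,
                            int(rng.integers(1, 5))) for _ in range(50)]
        [table] = count_cooccurrences(recs, context_window=2)
        for (c, x), v in table.counts.items():
            assert table.counts[(x, c)] == v


def _yearly(year, pairs):
    return YearlyCooccurrence(year, Counter(pairs))


class TestWindowAndFilter:
    def test_sliding_windows_stride_one(self):
        yearly = [_yearly(y, {("a", "b"): 200, ("b", "a"): 200})
                  for y in range(1950, 1961)]
        windows, vocab = window_and_filter(yearly, window_width_years=10,
                                           min_count=100)
        assert [w.window_start_year for w in windows] == [1950, 1951]
        assert vocab.lemmas == ("a", "b")

    def test_mass_conservation(self):
        yearly = [_yearly(y, {("a", "b"): 10 + y % 3, ("b", "a"): 10 + y % 3})
                  for y in range(2000, 2012)]
        windows, _ = window_and_filter(yearly, window_width_years=10,
                                       min_count=1)
        for w in windows:
            expected = sum(10 + y % 3 for y in range(
                w.window_start_year, w.window_start_year + 10))
            assert w.counts[("a", "b")] == expected

    def test_min_count_in_every_window(self):
        # lemma c totals 99 in the first window, 500 in the second
        yearly = []
        for y in range(2000, 2011):
            pairs = {("a", "b"): 500, ("b", "a"): 500}
            if y == 2000:
                pairs[("c", "a")] = 99
            elif y == 2010:
                pairs[("c", "a")] = 500
            yearly.append(_yearly(y, pairs))
        windows, vocab = window_and_filter(yearly, window_width_years=10,
                                           min_count=100)
        assert "c" not in vocab.lemmas
        for w in windows:
            assert all("c" not in pair for pair in w.counts)

    def test_single_window_threshold(self):
        yearly = [_yearly(2000, {("a", "a"): 150, ("b", "b"): 99})]
        windows, vocab = window_and_filter(yearly, window_width_years=1,
                                           min_count=100)
        assert vocab.lemmas == ("a",)

    def test_empty_vocabulary_fatal(self):
        yearly = [_yearly(2000, {("a", "b"): 1})]
        with pytest.raises(ValueError, match="survivor"):
            window_and_filter(yearly, window_width_years=1, min_count=100)


class TestSubsamplePairs:
    def _window(self, counts):
        return corpus.WindowedCooccurrence(2000, 10, Counter(counts))

    def test_total_is_exactly_n_c(self, rng):
        w = self._window({("a", "b"): 60, ("c", "d"): 40})
        for n_c in (1, 10, 99):
            assert subsample_pairs(w, n_c, rng).total() == n_c

    def test_hypergeometric_expectation(self):
        w = self._window({("a", "b"): 60, ("c", "d"): 40})
        draws = np.array([subsample_pairs(w, 10, seed).counts[("a", "b")]
                          for seed in range(1000)])
        # E = 6, Var = 10*(0.6*0.4)*(90/99) ≈ 2.18
        se = np.sqrt(2.18 / 1000)
        assert abs(draws.mean() - 6.0) < 3 * se

    def test_n_c_equals_total_is_identity(self, rng):
        w = self._window({("a", "b"): 3, ("b", "a"): 5})
        assert subsample_pairs(w, 8, rng).counts == w.counts

    def test_oversampling_fatal(self, rng):
        with pytest.raises(ValueError, match="N_c"):
            subsample_pairs(self._window({("a", "b"): 3}), 10, rng)

    def test_deterministic_per_seed(self):
        w = self._window({(a, b): 10 for a in "abc" for b in "abc"})
        assert (subsample_pairs(w, 30, 5).counts
                == subsample_pairs(w, 30, 5).counts)


class TestShuffleTimeLabels:
    def _tables(self, n=6):
        return [_yearly(2000 + i, {("a", "b"): i + 1}) for i in range(n)]

    def test_multiset_preserved_and_deterministic(self):
        tables = self._tables()
        out1 = shuffle_time_labels(tables, 3)
        out2 = shuffle_time_labels(tables, 3)
        assert [t.counts for t in out1] == [t.counts for t in out2]
        assert sorted(t.counts[("a", "b")] for t in out1) == list(range(1, 7))
        assert [t.year for t in out1] == [t.year for t in tables]

    def test_inverse_permutation_restores(self):
        tables = self._tables()
        out = shuffle_time_labels(tables, 3)
        perm = [next(i for i, t in enumerate(tables)
                     if t.counts == o.counts) for o in out]
        restored = [None] * len(tables)
        for pos, src in enumerate(perm):
            restored[src] = out[pos]
        assert [t.counts for t in restored] == [t.counts for t in tables]

    def test_two_years_both_orders_occur(self):
        tables = self._tables(2)
        seen = {shuffle_time_labels(tables, s)[0].counts[("a", "b")]
                for s in range(40)}
        assert seen == {1, 2}


def test_cooccurrence_tsv_roundtrip(tmp_path):
    w = corpus.WindowedCooccurrence(
        1990, 10, Counter({("a", "b"): 3, ("b", "a"): 3, ("c", "c"): 1}))
    path = tmp_path / "window.tsv"
    write_cooccurrence_tsv(w, path, seed=7)
    back = read_cooccurrence_tsv(path)
    assert back.counts == w.counts
    assert back.window_start_year == 1990
    assert back.window_width_years == 10
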