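# semdrift

Anomalous-diffusion analysis of word-meaning trajectories from diachronic
word embeddings.

## The problem

How fast, and in what statistical sense, do word meanings change?  Under
the distributional hypothesis a word's meaning is summarized by its
co-occurrence statistics, which a skip-gram (word2vec) embedding compresses
into a position in a D-dimensional semantic space.  With time-labeled
co-occurrence data (e.g. the Google Books Ngram corpus), each word traces a
stochastic trajectory x(t) through that space, and the ensemble of
trajectories can be classified like particle tracks in physics: by the
anomalous diffusion exponent α of the mean squared displacement,

    ⟨|Δx|²⟩(t) ∼ t^α,    Δx = x(t) − x(0).

α = 1 is ordinary diffusion (random walk); α < 1 is subdiffusion, which
implies temporal correlations or other non-trivial microscopic rules in
how meanings move.  Semantic trajectories measured this way are strongly
subdiffusive (α ≈ 0.4–0.5 across major Indo-European languages), and the
package exists to make every step of that measurement explicit, testable,
and falsifiable against null models.

The pipeline is delicate because embeddings are only identified up to a
symmetry: any map that preserves all word–context dot products leaves the
training objective unchanged.  Requiring the total word-cloud size
Tr V(W) — the trace of the empirical covariance of word positions — to be
constant over time restricts that freedom to the orthogonal group O(D).
The package therefore (i) trains M independent embeddings per time window
and averages them after generalized-Procrustes alignment, (ii) chain-aligns
the averaged embeddings across time with analytic orthogonal Procrustes
maps, R = argmin_{Q∈O(D)} ‖W′Q − W‖_F, and (iii) compares every measured
exponent against trajectory-randomization null models and synthetic
ensembles of known α.

## What's in the package

| module | role |
| --- | --- |
| `semdrift.corpus` | n-gram TSV parsing, Snowball stemming + stopwords, anchor-convention co-occurrence counting, sliding windows, vocabulary filtering, subsampling to constant N_c, time-label reshuffling |
| `semdrift.embedding` | SGNS training from pair multisets (online SGD, JIT-compiled, bit-reproducible per seed), ensembles of M runs |
| `semdrift.alignment` | cloud size Tr V, orthogonal Procrustes, within-window align-and-average, across-time chain alignment, cloud-size equalization |
| `semdrift.diffusion` | squared displacements, ensemble MSD, log-log exponent fits: ensemble ⟨α⟩ and per-word mean ᾱ |
| `semdrift.randomization` | step-size/direction decomposition and the 4×3 grid of randomization null models |
| `semdrift.synthetic` | exact fBm ensembles (covariance factorization), constant-cloud-size random walks, latent-drift corpora with known ground truth |
| `semdrift.pipeline` | corpus → embeddings → alignment → exponents orchestration |

The public face is the importable API plus the narrative scripts in
`examples/` (one per capability); the package is meant to be driven from
Python.

## Worked example

`examples/fbm_recovery.py` generates exact fractional Brownian motion
ensembles (Hurst H = α/2) and asks the estimator to recover the exponent:

```
target α   fitted ⟨α⟩   r²
  0.3        0.308      0.9962
  0.5        0.508      0.9987
  0.8        0.808      0.9995
  1.0        1.007      0.9997
```

Each row is 1000 trajectories with 50 time points; the fitted slope of the
ensemble MSD in log-log coordinates recovers the generating exponent to
within a few hundredths, with r² close to 1.

`examples/alignment_control.py` runs the key methodological control: a
random walk under the constant-cloud-size constraint, pushed through the
full temporal alignment, still fits

```
fitted ensemble exponent : 0.969 (r² = 0.9998)
```

i.e. maximal smoothing applied to uncorrelated motion does not manufacture
subdiffusion.  `examples/randomization_grid.py` prints the Table-1-style
null-model grid on a long-memory input, `examples/ngram_preprocessing.py`
walks the text-processing stage on a miniature n-gram file, and
`examples/latent_corpus_pipeline.py` runs the whole chain on a synthetic
corpus whose words drift by fBm(α = 0.5) — the drifting corpus yields a
clearly subdiffusive exponent (⟨α⟩ ≈ 0.24 at that scale) while a static
corpus shows only the flat embedding-noise floor (⟨α⟩ ≈ 0.05).

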