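# Methods

This note records the models, conventions and numerical choices behind
`semdrift`, in the order the pipeline applies them, together with the
reasoning for choices the underlying method leaves open.

## Trajectory model and the exponent

Word positions x_i(t) live in a D-dimensional embedding space; time is the
index of the sliding corpus window (one step = one year of window shift).
The central statistic is the anomalous diffusion exponent α of the
ensemble mean squared displacement from the origin,

    MSD(t) = (1/N) Σ_i |x_i(t) − x_i(0)|² ∼ t^α.

Two averages are computed and deliberately kept distinct: the ensemble
exponent ⟨α⟩ (average squared displacements first, fit once) and the mean
exponent ᾱ (fit each word, average the fits).  They agree for homogeneous
ensembles and differ informatively for heterogeneous ones.  Fits are
unweighted ordinary least squares of log₁₀ MSD on log₁₀ lag — the simplest
reproducible choice; the fitting range is a parameter everywhere, with
"all lags" the default and a pre-saturation rule (below) for confined
ensembles.  Exponents are invariant to linear rescaling of time and of
space, which the test suite asserts.

Lags with zero MSD (possible for single words) are dropped from that
word's fit because their logarithm is undefined; a word needs at least
three usable lags or it is excluded and counted.

## Corpus processing

* **Input format.**  Google Books Ngram v2 TSV (`ngram TAB year TAB
  match_count TAB volume_count`), plain or gzipped.  Malformed lines are
  skipped and counted, never fatal.
* **Normalization.**  Lowercase → stopword removal (matched on the raw
  lowercased token) → Snowball stemming.  The English (Porter2) stemmer is
  implemented in-package and verified against hand-traced runs of the
  published algorithm; only English is currently supported and the error
  message lists the supported languages.  Stems are equivalence-class
  labels, not dictionary lemmas — which is all the counting needs.
* **Anchor convention.**  N-gram files present overlapping text windows,
  so counting all within-record pairs would double count.  Each record
  emits pairs only between its *first* token and tokens at distance
  1..w (default w = 2), in both directions: each text position anchors
  exactly one record, so each co-occurrence is counted once.  Distances
  are measured on the post-removal (stopword-free) sequence.  Self-pairs
  of identical stems are kept; removing them would bias frequent words.
* **Windows and vocabulary.**  Years are merged into width-10, stride-1
  sliding windows; the vocabulary keeps stems with at least 100
  occurrences in *every* window (both thresholds configurable), ordered
  lexicographically for reproducible indices.
* **Subsampling.**  Each window is reduced to exactly N_c co-occurrence
  tokens (default 10⁷ at full scale) by a multivariate hypergeometric
  draw — sampling without replacement preserves the empirical pair
  distribution when N_c is close to the window total.  Constant N_c
  removes the systematic growth of the corpus over time, which would
  otherwise masquerade as semantic change.
* **Time-label reshuffle.**  A uniform permutation of the year → table
  mapping; any "drift" surviving it is an artifact of the downstream
  pipeline.

## Skip-gram training

The SGNS objective scores log p(j|i) ∝ v_i·w_j and trains each observed
(center, context) pair against k negatives from the unigram context
distribution raised to the 0.75 power.  Because subsampling has already
destroyed text order, training consumes the pair multiset directly: each
sampled co-occurrence is one positive example.

Hyperparameters the method's description leaves open are set to the
community defaults and flagged in `SGNSConfig`: k = 5 negatives, 5 epochs,
initial learning rate 0.025 decayed linearly to 10⁻⁴, word vectors
initialized uniform in [−0.5/D, 0.5/D], context vectors at zero.
Optimization is *online* SGD in the classic word2vec update order (context
rows updated immediately within an example, the center row once), with the
inner loop JIT-compiled.  Mini-batched variants that sum per-row gradients
were rejected: with small vocabularies a row collects many conflicting
stale-gradient updates per batch and training diverges.  All randomness
flows from one seeded generator, so a run is bit-reproducible
single-threaded.

## Alignment

Constant cloud size Tr V(W) = Σ_j Var_i(W_ij) (population convention,
divisor N) restricts the embedding symmetry group to O(D); the package
enforces and exploits exactly that:

* every matrix is centered once at module entry (the symmetry class is
  translation-invariant, and orthogonal Procrustes assumes centered data);
* pairwise alignment is the analytic SVD solution R = UVᵀ of W_srcᵀW_ref,
  with reflections allowed (the constraint pins O(D), not SO(D));
  degenerate all-zero input returns the identity with a warning;
* within a window, the M runs are aligned by generalized Procrustes:
  reference = run 0, then alternately align-all and re-average until the
  reference moves less than 10⁻⁶ mean per-word displacement.  Each
  half-step solves a least-squares subproblem, so the total residual is
  non-increasing.  On trained ensembles convergence is linear with rate
  ≈ 0.98 per sweep, so the iteration cap is generous (1000); sweeps cost
  only a few D×D SVDs.
* across time, window t is aligned to the already-aligned window t−1
  (sequential chaining, matching the left-to-right construction of the
  diachronic embedding); aligning every window directly to window 0 is
  available as a sensitivity mode.  Per-step maps are stored so the chain
  is exactly reproducible.
* cloud-size equalization (rescaling every window to window 0's Tr V) is
  on by default: constant N_c only approximately enforces the constraint,
  and the orthogonal symmetry argument assumes it exactly.

## Randomization null models

Trajectories are decomposed into step sizes s = |x(t+1) − x(t)| and unit
directions u = step/s; zero-length steps receive a seeded uniform random
unit direction so size-randomized reconstructions stay well defined.  The
grid crosses four size modes (random = per-word |Normal(mean_i, sd_i)|
draws; sampled = pooled resampling across words; shuffled = within-word
permutation; original) with three direction modes (random = uniform on the
sphere; shuffled = within-word permutation; original).  Negative normal
draws are reflected to their absolute value — the distribution of step
*sizes* is supported on the non-negative axis and reflection is the
minimal intervention; this choice is recorded in the grid metadata.
Shuffling is strictly within-word.  Each cell derives its own seed from
the master seed and the cell label, so cells reproduce in isolation, and
the (original, original) cell bypasses decomposition entirely so it equals
the direct pipeline output bit for bit.

Per-word exponents are withheld (NaN) for direction-shuffled cells: with
sizes largely preserved, shuffling directions pins the total displacement,
and per-word fits to such constrained series are biased by the choice of
fitting range.

## Synthetic generators

* **fBm.**  Fractional Gaussian noise has autocovariance
  γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}), H = α/2; increments are
  drawn exactly through a Cholesky factor of that matrix (eigen-decomposition
  fallback near H → 1) and cumulatively summed.  Exact factorization was
  chosen over spectral approximation because trajectory lengths here are
  ≤ ~100 and exactness removes one bias source from recovery tests.
* **Constrained random walk.**  iid steps (|Normal(s, s/3)| sizes, uniform
  directions); with the cloud constraint, walkers start spread in a
  Gaussian cloud and after every step all positions are rescaled about the
  centroid so Tr V keeps its initial value.  The constraint only affects
  the ensemble as displacements approach the cloud radius; the default
  radius (10 step units) has a unit-step walk traverse about half the
  cloud over a 50-step epoch, so the confined control probes alignment
  rather than confinement.  At long times the MSD saturates at 2R²
  (displacement √2 × radius), which the suite verifies separately at small
  radius.
* **Latent-drift corpus.**  n words carry latent vectors (init s.d.
  d^{-1/4} per coordinate, giving unit-variance dot products) whose word
  and context vectors share one drift process (rigid co-drift, isolating
  semantic motion).  Per window, co-occurrences are emitted with centers
  from a Zipf(1) (or uniform) law and contexts from a max-shifted softmax
  over v_i·w_j — the same functional form the skip-gram model assumes, so
  recovery is well-posed in the large-sample limit.  The default drift
  (RMS 0.6 latent units per step) lets an fBm(α = 0.5) word traverse about
  half the cloud radius over 20 windows, the displacement-to-cloud ratio
  real word clouds exhibit over comparable spans.

## Problem sizes used in validation

The validation suite runs at desk scale by design: exponent recovery and
null grids use 500–1000 trajectories of 50 steps; the end-to-end corpus
test uses 500 words, latent dimension 50, T = 20 windows, M = 5 embedding
runs per window, 10⁵ co-occurrences per window, embedding dimension 50 and
3 epochs.  Full-scale corpus analysis (10⁷ pairs/window, D = 300, M = 80)
uses the identical code paths; only the configuration differs.

At desk scale the end-to-end test asserts *detection*, not exact recovery:
the fitted ⟨α⟩ for an fBm(α = 0.5) latent corpus (≈ 0.25 at these sizes)
must be subdiffusive and clearly above the static-corpus noise floor
(≈ 0.02–0.05).  The attenuation is expected: the embedding noise floor
adds a roughly lag-independent offset to the MSD, flattening the log-log
slope; absolute recovery improves with more co-occurrences, runs, and
windows.

## Statistical notes and limitations

* On fBm input the random-sizes and shuffled-sizes nulls coincide in
  expectation (fBm step sizes are nearly uncorrelated in time), so the
  information ordering random ≥ shuffled is asserted on multi-seed means
  with a 2-standard-error allowance; shuffled ≥ original is a large,
  strict gap.  On real corpora, where size sequences are correlated, the
  ordering is strict.
* The synthetic corpus does not emulate several features of real n-gram
  data: vocabulary turnover (words entering/leaving the frequency
  threshold), burstiness and topic structure of co-occurrences,
  frequency-dependent embedding bias beyond the Zipf frequency law, OCR
  noise, or the uneven growth of the corpus over time.  Passing tests
  therefore validate the estimator and pipeline mechanics, not the
  linguistic claim itself.
* Only the English stemmer is implemented; other languages require adding
  their Snowball variants.
* Per-word trajectories are jointly determined by a global objective;
  single-word exponents are noisy and only ensemble summaries are
  interpreted.
* Time-averaged MSD, ergodicity-breaking statistics, and likelihood-based
  fBm estimators are out of scope; the exponent is always a log-log OLS
  slope.
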