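"""Skip-gram negative-sampling (SGNS) embeddings from co-occurrence pairs.

The model represents word i by a word vector v_i and a context vector w_i,
scoring the log-probability of seeing context j with center i as
log p(j|i) ∝ v_i·w_j.  Training maximizes log σ(v_i·w_j) for each observed
(center, context) pair against k noise contexts drawn from the unigram
context distribution raised to a fractional power:

    ℓ = log σ(v_i·w_j) + Σ_{n=1..k} log σ(−v_i·w_n).

Because the pipeline subsamples co-occurrences to a fixed budget N_c, text
order is already lost; training therefore consumes the pair *multiset*
directly — each sampled co-occurrence is one positive example — rather than
a token stream.  Optimization is online SGD with the classic word2vec
update order (context rows updated immediately, the center row once per
example) and a linearly decayed learning rate; the inner loop is JIT
compiled.  All randomness (initialization, example order, negative draws)
comes from one seeded generator, so a fixed seed reproduces the run bit
for bit in single-threaded execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import SGNSConfig
from .corpus import Vocabulary, WindowedCooccurrence

_MIN_LR_FRACTION = 1e-4 / 0.025


@dataclass
class TrainingPairs:
    """Directed (center, context) index pair multiset over a vocabulary."""

    centers: np.ndarray    # (P,) int indices
    contexts: np.ndarray   # (P,) int indices
    counts: np.ndarray     # (P,) positive ints
    n_words: int

    def __post_init__(self) -> None:
        for arr in (self.centers, self.contexts):
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_words):
                raise ValueError("pair index outside vocabulary")

    @classmethod
    def from_window(cls, window: WindowedCooccurrence,
                    vocab: Vocabulary) -> "TrainingPairs":
        centers, contexts, counts = window.to_arrays(vocab)
        return cls(centers, contexts, counts, len(vocab))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def context_counts(self) -> np.ndarray:
        """Unigram context occurrence counts over the vocabulary."""
        return np.bincount(self.contexts, weights=self.counts,
                           minlength=self.n_words)


@dataclass
class EmbeddingRun:
    """One trained embedding: word and context matrices plus provenance."""

    word_vectors: np.ndarray     # (N, D)
    context_vectors: np.ndarray  # (N, D)
    seed: int
    config: SGNSConfig
    epoch_losses: np.ndarray = field(default=None)


@dataclass
class EmbeddingEnsemble:
    """M independent runs of one time window over a shared vocabulary."""

    runs: list
    vocabulary: Vocabulary | None = None
    window_label: int | None = None

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("ensemble needs at least one run")
        shapes = {r.word_vectors.shape for r in self.runs}
        if len(shapes) != 1:
            raise ValueError("runs disagree on vocabulary size or dimension")

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def build_negative_table(context_counts: np.ndarray,
                         power: float = 0.75) -> np.ndarray:
    """Noise distribution for negative sampling: p_j ∝ count_j^power."""
    counts = np.asarray(context_counts, dtype=float)
    if not 0.0 < power <= 1.0:
        raise ValueError("power must lie in (0, 1]")
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    weights = counts ** power
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero context counts")
    return weights / total


@njit(cache=False)
def _sgns_epoch(word, ctx, centers, contexts, negatives,
                lr_start, lr_slope):  # pragma: no cover - jit kernel
    """One online-SGD pass; returns the summed negative log-likelihood.

    Classic word2vec update order per example: the gradient on the center
    vector is accumulated over the positive and all negative targets while
    each context row is updated immediately, then the center row is
    updated once.
    """
    n_examples = centers.shape[0]
    k = negatives.shape[1]
    dim = word.shape[1]
    grad_center = np.empty(dim)
    loss = 0.0
    for e in range(n_examples):
        lr = lr_start + lr_slope * e
        i = centers[e]
        for d in range(dim):
            grad_center[d] = 0.0
        for t in range(k + 1):
            j = contexts[e] if t == 0 else negatives[e, t - 1]
            label = 1.0 if t == 0 else 0.0
            dot = 0.0
            for d in range(dim):
                dot += word[i, d] * ctx[j, d]
            if dot >= 0.0:
                f = 1.0 / (1.0 + np.exp(-dot))
            else:
                ex = np.exp(dot)
                f = ex / (1.0 + ex)
            if t == 0:
                loss -= np.log(f + 1e-12)
            else:
                loss -= np.log(1.0 - f + 1e-12)
            g = (f - label) * lr
            for d in range(dim):
                grad_center[d] += g * ctx[j, d]
                ctx[j, d] -= g * word[i, d]
        for d in range(dim):
            word[i, d] -= grad_center[d]
    return loss


def train_sgns(pairs: TrainingPairs, config: SGNSConfig,
               seed: int = 0) -> EmbeddingRun:
    """Train one SGNS embedding on a pair multiset.

    Word vectors start uniform in [−0.5/D, 0.5/D]; context vectors start at
    zero.  Per epoch, the expanded example list is visited in a fresh
    random order; the learning rate decays linearly from its initial value
    to 1e-4·(lr/0.025) over the whole schedule.  The mean per-example loss
    of each epoch is recorded for convergence checks.
    """
    if pairs.n_words < 2:
        raise ValueError("vocabulary must contain at least two words")
    if pairs.total == 0:
        raise ValueError("empty training pair multiset")
    rng = np.random.default_rng(seed)
    n, dim = pairs.n_words, config.dim
    word = (rng.random((n, dim)) - 0.5) / dim
    ctx = np.zeros((n, dim))

    base_centers = np.repeat(pairs.centers, pairs.counts).astype(np.int64)
    base_contexts = np.repeat(pairs.contexts, pairs.counts).astype(np.int64)
    n_examples = base_centers.size
    noise = build_negative_table(pairs.context_counts(), config.noise_power)
    cum = np.cumsum(noise)
    cum[-1] = 1.0

    k = config.negative
    lr0 = config.learning_rate
    lr_min = lr0 * _MIN_LR_FRACTION
    total = config.epochs * n_examples
    losses = np.zeros(config.epochs)
    done = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n_examples)
        negatives = np.searchsorted(
            cum, rng.random((n_examples, k))).astype(np.int64)
        lr_start = max(lr0 * (1.0 - done / total), lr_min)
        lr_end = max(lr0 * (1.0 - (done + n_examples) / total), lr_min)
        lr_slope = (lr_end - lr_start) / n_examples
        loss = _sgns_epoch(word, ctx, base_centers[order],
                           base_contexts[order], negatives,
                           lr_start, lr_slope)
        losses[epoch] = loss / n_examples
        done += n_examples
    return EmbeddingRun(word, ctx, seed, config, losses)


def train_ensemble(pairs: TrainingPairs, config: SGNSConfig,
                   master_seed: int = 0, n_runs: int = 80,
                   vocabulary: Vocabulary | None = None,
                   window_label: int | None = None) -> EmbeddingEnsemble:
    """Train M independent runs with seeds master_seed + run index."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = [train_sgns(pairs, config, seed=master_seed + m)
            for m in range(n_runs)]
    return EmbeddingEnsemble(runs, vocabulary, window_label)
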