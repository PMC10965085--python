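"""Ground-truth generators for pipeline validation.

Three generators cover the three validation layers of the trajectory
pipeline:

* :func:`generate_fbm` — exact fractional Brownian motion ensembles with a
  known anomalous diffusion exponent α = 2H, realized by Cholesky
  factorization of the fractional-Gaussian-noise covariance (exact, not a
  spectral approximation; trajectory lengths here are small enough that the
  O(T³) factorization is free).  Used for exponent-recovery tests.
* :func:`generate_random_walk` — iid-step walks, optionally with the
  word-cloud constraint: after every step all positions are rescaled about
  their centroid so the total cloud size Tr V stays at its initial value.
  This is the control ensemble for the alignment pipeline: maximal
  smoothing applied to uncorrelated motion must still fit α ≈ 1.
* :func:`generate_latent_corpus` — a corpus whose words move in a latent
  semantic space by a known drift process and emit co-occurrence counts
  through the same softmax-of-dot-products form the skip-gram model
  assumes, so the full corpus → embedding → alignment → exponent pipeline
  can be scored against known ground truth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .corpus import Vocabulary, WindowedCooccurrence


@dataclass(frozen=True)
class FBMParams:
    """Fractional Brownian motion ensemble parameters.

    ``target_alpha`` is the MSD exponent; the Hurst parameter is H = α/2.
    ``n_times`` is the number of trajectory time points T (T − 1 steps).
    """

    target_alpha: float
    n_times: int = 50
    dims: int = 3
    n_traj: int = 1000
    step_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_alpha < 2.0:
            raise ValueError("target_alpha must lie in (0, 2)")
        if self.n_times < 2 or self.dims < 1 or self.n_traj < 1:
            raise ValueError("n_times, dims and n_traj must be positive")

    @property
    def hurst(self) -> float:
        return self.target_alpha / 2.0


def fgn_covariance(hurst: float, n_steps: int) -> np.ndarray:
    """Autocovariance matrix of fractional Gaussian noise.

    Entry (s, t) is γ(|s−t|) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) with
    k = |s−t|; γ(0) = 1.  Symmetric positive semidefinite for H ∈ (0, 1).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie in (0, 1)")
    k = np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps)))
    k = k.astype(float)
    two_h = 2.0 * hurst
    return 0.5 * ((k + 1) ** two_h - 2 * k ** two_h
                  + np.abs(k - 1) ** two_h)


def generate_fbm(params: FBMParams,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Exact fBm ensemble; returns positions of shape (T, n_traj, dims).

    Every dimension of every trajectory is an independent partial-sum path
    of fGn increments drawn through the Cholesky factor of the exact
    covariance, so the ensemble MSD is D·scale²·t^α by construction (up to
    sampling noise).  Trajectories start at the origin.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_steps = params.n_times - 1
    cov = fgn_covariance(params.hurst, n_steps)
    try:
        L = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        # H near 1 can make the matrix numerically semidefinite
        w, V = linalg.eigh(cov)
        if w.min() < -1e-8:
            raise
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    eps = rng.standard_normal((n_steps, params.n_traj * params.dims))
    increments = params.step_scale * (L @ eps)
    positions = np.vstack([
        np.zeros((1, params.n_traj * params.dims)),
        np.cumsum(increments, axis=0),
    ])
    return positions.reshape(params.n_times, params.n_traj, params.dims)


def _uniform_directions(rng: np.random.Generator, n: int,
                        dims: int) -> np.ndarray:
    """iid directions uniform on the (dims−1)-sphere."""
    v = rng.standard_normal((n, dims))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_random_walk(n_traj: int = 1000, n_times: int = 50,
                         dims: int = 300, step_scale: float = 1.0,
                         constant_cloud: bool = False,
                         cloud_radius: float = 10.0,
                         rng: np.random.Generator | int = 0) -> np.ndarray:
    """iid-step random walk ensemble; positions of shape (T, n_traj, dims).

    Step sizes are |Normal(step_scale, step_scale/3)| and directions uniform
    on the sphere.  Without the constraint, walkers start at the origin and
    the ensemble MSD is linear in t.  With ``constant_cloud``, walkers start
    spread in a Gaussian cloud of total variance cloud_radius² and after
    every step all positions are rescaled about their centroid so Tr V
    keeps its initial value — the same global constraint a constant-size
    word cloud imposes.  The constraint only affects the ensemble once
    displacements approach the cloud radius; the default radius is chosen
    so a unit-step walk traverses roughly half the cloud over a 50-step
    epoch, the regime in which the confined control is informative (the
    per-step contraction is then a small perturbation).  At long times the
    MSD saturates at 2·cloud_radius², i.e. displacements of √2 × radius.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    positions = np.empty((n_times, n_traj, dims))
    if constant_cloud:
        x = rng.standard_normal((n_traj, dims)) * (cloud_radius
                                                   / np.sqrt(dims))
        x -= x.mean(axis=0, keepdims=True)
        target = float(np.var(x, axis=0).sum())
        x *= cloud_radius / np.sqrt(target)
        target = cloud_radius ** 2
    else:
        x = np.zeros((n_traj, dims))
    positions[0] = x
    for t in range(1, n_times):
        sizes = np.abs(rng.normal(step_scale, step_scale / 3.0, n_traj))
        dirs = _uniform_directions(rng, n_traj, dims)
        x = x + sizes[:, None] * dirs
        if constant_cloud:
            centroid = x.mean(axis=0, keepdims=True)
            size = float(np.var(x, axis=0).sum())
            x = centroid + (x - centroid) * np.sqrt(target / size)
        positions[t] = x
    return positions


@dataclass(frozen=True)
class LatentCorpusParams:
    """Latent-drift corpus: words move in meaning space, counts follow.

    Word i's latent vector v_i(t) and context vector w_i(t) share one drift
    process instance (rigid co-drift), isolating semantic motion from
    context motion.  At each window, ``pairs_per_window`` co-occurrences are
    emitted: the center is drawn from the frequency law, the context from a
    softmax over v_center · w_context.  ``drift_scale`` is the RMS per-step
    displacement of a word in latent units; the initial cloud has unit
    dot-product scale (init standard deviation d^{-1/4} per coordinate, so
    Tr V = √d).  The default drift lets an fBm(α = 0.5) word traverse about
    half the cloud radius over 20 windows — the displacement-to-cloud
    ratio the real word clouds exhibit over comparable spans.
    """

    n_words: int = 500
    latent_dim: int = 50
    n_windows: int = 20
    drift_process: str = "fbm"        # "fbm" | "random_walk" | "static"
    target_alpha: float = 0.5         # exponent of the fbm drift
    drift_scale: float = 0.6
    pairs_per_window: int = 100_000
    frequency_law: str = "zipf"       # "zipf" | "uniform"
    zipf_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.pairs_per_window < self.n_words:
            raise ValueError("pairs_per_window must be >= n_words")
        if self.drift_process not in ("fbm", "random_walk", "static"):
            raise ValueError("drift_process must be fbm|random_walk|static")
        if self.frequency_law not in ("zipf", "uniform"):
            raise ValueError("frequency_law must be zipf|uniform")


def _drift_increments(params: LatentCorpusParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-step latent displacements, shape (T−1, n_words, latent_dim)."""
    n_steps = params.n_windows - 1
    shape = (n_steps, params.n_words, params.latent_dim)
    per_dim = params.drift_scale / np.sqrt(params.latent_dim)
    if params.drift_process == "static":
        return np.zeros(shape)
    if params.drift_process == "random_walk":
        return per_dim * rng.standard_normal(shape)
    cov = fgn_covariance(params.target_alpha / 2.0, n_steps)
    L = linalg.cholesky(cov, lower=True)
    eps = rng.standard_normal((n_steps,
                               params.n_words * params.latent_dim))
    return (per_dim * (L @ eps)).reshape(shape)


def generate_latent_corpus(params: LatentCorpusParams):
    """Emit per-window co-occurrence tables from a drifting latent space.

    Returns ``(windows, vocab, truth)`` where ``windows`` is a list of
    :class:`WindowedCooccurrence` (one per window, each totalling exactly
    pairs_per_window), ``vocab`` the lexicographically ordered synthetic
    vocabulary, and ``truth`` the (T, n_words, latent_dim) ground-truth
    latent word trajectories for recovery scoring.
    """
    rng = np.random.default_rng(params.seed)
    n, d, T = params.n_words, params.latent_dim, params.n_windows
    scale = d ** -0.25          # unit-variance dot products
    v0 = rng.standard_normal((n, d)) * scale
    w0 = rng.standard_normal((n, d)) * scale
    inc = _drift_increments(params, rng)
    truth = np.empty((T, n, d))
    truth[0] = v0
    for t in range(1, T):
        truth[t] = truth[t - 1] + inc[t - 1]

    if params.frequency_law == "zipf":
        ranks = np.arange(1, n + 1, dtype=float)
        freq = ranks ** -params.zipf_exponent
    else:
        freq = np.ones(n)
    freq /= freq.sum()

    width = len(str(n - 1))
    vocab = Vocabulary(tuple(f"w{i:0{width}d}" for i in range(n)))

    windows = []
    w_ctx = w0.copy()
    for t in range(T):
        if t > 0:
            w_ctx = w_ctx + inc[t - 1]      # rigid co-drift
        logits = truth[t] @ w_ctx.T
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        center_counts = rng.multinomial(params.pairs_per_window, freq)
        counts: Counter = Counter()
        for i in np.nonzero(center_counts)[0]:
            ctx_counts = rng.multinomial(center_counts[i], probs[i])
            for j in np.nonzero(ctx_counts)[0]:
                counts[(vocab.lemmas[i], vocab.lemmas[j])] = int(
                    ctx_counts[j])
        windows.append(WindowedCooccurrence(t, 1, counts))
    return windows, vocab, truth
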