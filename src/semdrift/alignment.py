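"""Orthogonal alignment of embedding ensembles into word trajectories.

A skip-gram embedding is only identified up to a transformation that leaves
all word–context dot products invariant.  Requiring in addition that the
total word-cloud size Tr V(W) — the trace of the empirical covariance of
word positions — stays constant over time restricts that freedom to the
orthogonal group O(D).  This module removes the orthogonal degeneracy in two
stages, mirroring how the diachronic pipeline is assembled:

1. the M independent embedding runs of one time window are iteratively
   aligned to their evolving mean (generalized Procrustes) and averaged,
   suppressing training stochasticity;
2. the averaged per-window embeddings are chain-aligned through time, each
   window to its already-aligned predecessor, producing maximally smoothed
   word trajectories.

Each pairwise alignment is the analytic orthogonal Procrustes solution
R = argmin_{Q in O(D)} ||W' Q − W||_F, obtained from the SVD of W'ᵀ W.
Reflections are allowed: the symmetry class is all of O(D), not SO(D).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corpus import Vocabulary

logger = logging.getLogger(__name__)

ORTHOGONALITY_ATOL = 1e-8


@dataclass
class DiachronicEmbedding:
    """Aligned, averaged word positions over time.

    ``positions`` has shape (T, N, D); row n of slice t is word n's position
    in window t.  ``maps`` stores the per-step orthogonal matrices actually
    applied during chain alignment, so the chain is exactly reproducible.
    """

    positions: np.ndarray
    window_labels: np.ndarray
    vocabulary: Vocabulary | None = None
    maps: list | None = None

    @property
    def n_windows(self) -> int:
        return self.positions.shape[0]


def center(W: np.ndarray) -> np.ndarray:
    """Remove the column means (the cloud centroid)."""
    W = np.asarray(W, dtype=float)
    return W - W.mean(axis=0, keepdims=True)


def cloud_size(W: np.ndarray) -> float:
    """Total variance Tr V(W) of the word cloud (population convention).

    Equals the sum over dimensions of the variance of word positions along
    that dimension, with divisor N.  Invariant under any orthogonal map of
    the rows, which is exactly why constant cloud size pins the symmetry
    class to O(D).
    """
    W = np.asarray(W, dtype=float)
    return float(np.var(W, axis=0, ddof=0).sum())


def procrustes_rotation(W_src: np.ndarray, W_ref: np.ndarray) -> np.ndarray:
    """Analytic solution of the orthogonal Procrustes problem.

    Returns the D×D orthogonal R minimizing ||W_src R − W_ref||_F over O(D):
    with U S Vᵀ the SVD of W_srcᵀ W_ref, R = U Vᵀ.  Inputs are assumed
    centered.  A degenerate (all-zero) input yields the identity with a
    warning.
    """
    W_src = np.asarray(W_src, dtype=float)
    W_ref = np.asarray(W_ref, dtype=float)
    if W_src.shape != W_ref.shape:
        raise ValueError(f"shape mismatch {W_src.shape} vs {W_ref.shape}")
    M = W_src.T @ W_ref
    if not np.any(M):
        logger.warning("degenerate Procrustes input; returning identity")
        return np.eye(W_src.shape[1])
    U, _, Vt = np.linalg.svd(M)
    return U @ Vt


def is_orthogonal(R: np.ndarray, atol: float = ORTHOGONALITY_ATOL) -> bool:
    R = np.asarray(R, dtype=float)
    return bool(np.max(np.abs(R @ R.T - np.eye(R.shape[0]))) <= atol
                and abs(abs(np.linalg.det(R)) - 1.0) <= 1e-6)


def alignment_residual(runs, reference: np.ndarray) -> float:
    """Σ_m ||W_m R_m − reference||²_F with each R_m the optimal map."""
    total = 0.0
    for W in runs:
        R = procrustes_rotation(W, reference)
        total += float(np.sum((W @ R - reference) ** 2))
    return total


def align_runs_and_average(runs, tol: float = 1e-6,
                           max_iter: int = 1000) -> np.ndarray:
    """Generalized Procrustes: align all runs to their mean and average.

    The reference starts at (centered) run 0; each sweep aligns every run to
    the reference and replaces the reference by the mean of the aligned
    runs.  Each half-step solves a least-squares subproblem, so the total
    residual is non-increasing.  Stops when the mean per-word displacement
    of the reference falls below ``tol``.  On trained ensembles the
    iteration converges linearly at a rate close to one, so the cap is
    generous; each sweep costs only a few D×D SVDs.
    """
    runs = [center(np.asarray(W, dtype=float)) for W in runs]
    if not runs:
        raise ValueError("empty ensemble")
    if len(runs) == 1:
        return runs[0]
    reference = runs[0]
    n_words = reference.shape[0]
    for _ in range(max_iter):
        aligned = [W @ procrustes_rotation(W, reference) for W in runs]
        new_ref = np.mean(aligned, axis=0)
        shift = float(np.mean(np.linalg.norm(new_ref - reference, axis=1)))
        reference = new_ref
        if shift < tol:
            break
    else:
        logger.warning("generalized alignment did not converge in %d "
                       "iterations (last shift %.3g)", max_iter, shift)
    return reference


def equalize_cloud_size(matrices) -> list[np.ndarray]:
    """Rescale each centered matrix so Tr V matches window 0's.

    Enforces exactly the constant-cloud-size constraint that defines the
    orthogonal symmetry class; subsampling to constant N_c only enforces it
    approximately.
    """
    matrices = [np.asarray(W, dtype=float) for W in matrices]
    sizes = [cloud_size(W) for W in matrices]
    if any(s <= 0 for s in sizes):
        raise ValueError("zero cloud size; cannot equalize")
    target = sizes[0]
    return [W * np.sqrt(target / s) for W, s in zip(matrices, sizes)]


def chain_align_time(matrices, window_labels=None,
                     vocabulary: Vocabulary | None = None,
                     equalize: bool = True,
                     to_first: bool = False) -> DiachronicEmbedding:
    """Chain the averaged per-window embeddings into trajectories.

    Window 0 is the fixed reference; window t ≥ 1 is aligned to the
    already-aligned window t−1 (or directly to window 0 when ``to_first`` is
    set, a sensitivity-check mode).  All matrices are centered first, and by
    default rescaled to a common cloud size.  Pure symmetry motion — window
    t equal to window t−1 times an orthogonal map — is removed entirely.
    """
    mats = [center(np.asarray(W, dtype=float)) for W in matrices]
    if len(mats) < 2:
        raise ValueError("need at least two windows")
    shape = mats[0].shape
    for W in mats:
        if W.shape != shape:
            raise ValueError("all windows must share vocabulary and D")
    if vocabulary is not None and len(vocabulary) != shape[0]:
        raise ValueError("vocabulary size does not match matrices")
    if equalize:
        mats = equalize_cloud_size(mats)
    aligned = [mats[0]]
    maps = [np.eye(shape[1])]
    for t in range(1, len(mats)):
        ref = aligned[0] if to_first else aligned[t - 1]
        R = procrustes_rotation(mats[t], ref)
        aligned.append(mats[t] @ R)
        maps.append(R)
    labels = (np.arange(len(mats)) if window_labels is None
              else np.asarray(window_labels))
    return DiachronicEmbedding(np.stack(aligned), labels, vocabulary, maps)
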