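"""Mean squared displacement and anomalous diffusion exponents.

Word trajectories x_i(t) in the D-dimensional embedding space are treated as
an ensemble of stochastic trajectories.  The displacement from the origin,
Δx = x(t) − x(0), obeys ⟨|Δx|²⟩ ∼ t^α with anomalous diffusion exponent α:
α = 1 is ordinary diffusion, α < 1 subdiffusion, α > 1 superdiffusion.

Two ensemble summaries are computed, which need not agree for heterogeneous
ensembles:

* the ensemble-average exponent ⟨α⟩ — average |Δx_i(t)|² over words first,
  then fit one exponent to the mean squared displacement curve;
* the mean exponent ᾱ — fit an exponent α_i to each word's own squared
  displacement series, then average the α_i.

All fits are unweighted least squares of log10 MSD on log10 lag.  Time is in
window-index units; exponents are invariant to linear time rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class MSDCurve:
    """Ensemble mean squared displacement per lag (lag 0 excluded)."""

    lags: np.ndarray
    values: np.ndarray
    n_words: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ExponentFit:
    alpha: float
    log_prefactor: float       # log10 of the MSD at lag 1 under the fit
    fit_range: tuple[int, int]
    r_squared: float
    n_lags: int


@dataclass
class ExponentSummary:
    ensemble_alpha: float          # ⟨α⟩, fit to the ensemble MSD
    mean_alpha: float              # ᾱ, mean of per-word α_i
    per_word_alphas: np.ndarray
    per_word_r_squared: np.ndarray
    n_failed: int = 0
    ensemble_fit: ExponentFit | None = None
    word_indices: np.ndarray = field(default=None)  # words entering ᾱ


def squared_displacement(trajectories: np.ndarray) -> np.ndarray:
    """|x_i(t) − x_i(0)|² for t = 1..T−1; shape (N, T−1).

    ``trajectories`` has shape (T, N, D).  Distance is Euclidean in the
    D-dimensional embedding space.
    """
    X = np.asarray(trajectories, dtype=float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("trajectories must have shape (T>=2, N, D)")
    delta = X[1:] - X[0]
    return np.einsum("tnd,tnd->nt", delta, delta)


def ensemble_msd(sq_disp: np.ndarray) -> MSDCurve:
    """Average squared displacements over words at each lag."""
    sq = np.atleast_2d(np.asarray(sq_disp, dtype=float))
    values = sq.mean(axis=0)
    lags = np.arange(1, sq.shape[1] + 1)
    return MSDCurve(lags, values, sq.shape[0])


def fit_exponent(curve: MSDCurve | np.ndarray,
                 fit_range: tuple[int, int] | None = None) -> ExponentFit:
    """Fit ⟨|Δx|²⟩ ∼ t^α by OLS in log10–log10 coordinates.

    ``fit_range`` is an inclusive (min_lag, max_lag) interval; by default
    all lags 1..T−1 are used.  Lags with non-positive MSD are dropped with a
    warning (their logarithm is undefined); at least three usable lags are
    required.
    """
    if not isinstance(curve, MSDCurve):
        curve = ensemble_msd(np.atleast_2d(curve))
    lags, values = curve.lags, curve.values
    if fit_range is None:
        fit_range = (int(lags.min()), int(lags.max()))
    lo, hi = fit_range
    mask = (lags >= lo) & (lags <= hi)
    bad = mask & (values <= 0)
    if bad.any():
        logger.warning("dropping %d non-positive MSD values from fit",
                       int(bad.sum()))
        mask &= values > 0
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 positive lags in fit range {fit_range}; "
            f"have {int(mask.sum())}"
        )
    res = stats.linregress(np.log10(lags[mask]), np.log10(values[mask]))
    return ExponentFit(
        alpha=float(res.slope),
        log_prefactor=float(res.intercept),
        fit_range=(lo, hi),
        r_squared=float(res.rvalue ** 2),
        n_lags=int(mask.sum()),
    )


def per_word_exponents(trajectories: np.ndarray,
                       fit_range: tuple[int, int] | None = None,
                       ) -> ExponentSummary:
    """Fit α_i per word and ⟨α⟩ for the ensemble on the same fit range.

    Words whose individual fit fails (fewer than three positive lags in
    range) are excluded from ᾱ and counted in ``n_failed``.
    """
    sq = squared_displacement(trajectories)
    ens_fit = fit_exponent(ensemble_msd(sq), fit_range)
    alphas, r2s, kept = [], [], []
    n_failed = 0
    for i in range(sq.shape[0]):
        try:
            f = fit_exponent(ensemble_msd(sq[i:i + 1]), fit_range)
        except ValueError:
            n_failed += 1
            continue
        alphas.append(f.alpha)
        r2s.append(f.r_squared)
        kept.append(i)
    if not alphas:
        raise ValueError("exponent fit failed for every word")
    return ExponentSummary(
        ensemble_alpha=ens_fit.alpha,
        mean_alpha=float(np.mean(alphas)),
        per_word_alphas=np.array(alphas),
        per_word_r_squared=np.array(r2s),
        n_failed=n_failed,
        ensemble_fit=ens_fit,
        word_indices=np.array(kept),
    )


def presaturation_range(curve: MSDCurve, cloud_size: float,
                        min_lags: int = 3) -> tuple[int, int]:
    """Lag interval over which the MSD is still below the cloud radius.

    A cloud of total variance Tr V confines displacements: the MSD of an
    uncorrelated walk saturates near 2·Tr V (two orthogonal vectors of
    length equal to the cloud radius).  The pre-saturation interval keeps
    lags with MSD below Tr V, i.e. displacement below the cloud radius, and
    is the honest fitting window for confined ensembles.
    """
    below = curve.values < cloud_size
    if below.all():
        return (int(curve.lags.min()), int(curve.lags.max()))
    first_bad = int(np.argmin(below))
    hi = max(first_bad, min_lags)
    return (int(curve.lags.min()), int(curve.lags[hi - 1]))
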