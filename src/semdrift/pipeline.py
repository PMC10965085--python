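"""End-to-end orchestration: co-occurrence windows → exponent estimates.

Glues the stages together in the order the method prescribes: per window,
subsample to the fixed co-occurrence budget, train M independent skip-gram
embeddings, align them to their mean and average; then chain-align the
averaged embeddings across windows and fit anomalous diffusion exponents to
the resulting word trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import (DiachronicEmbedding, align_runs_and_average,
                        chain_align_time, cloud_size)
from .config import PipelineConfig
from .corpus import Vocabulary, WindowedCooccurrence, subsample_pairs
from .diffusion import (ExponentSummary, ensemble_msd, per_word_exponents,
                        presaturation_range, squared_displacement)
from .embedding import TrainingPairs, train_ensemble


@dataclass
class PipelineResult:
    diachronic: DiachronicEmbedding
    summary: ExponentSummary
    fit_range: tuple[int, int]


def embed_windows(windows, vocab: Vocabulary,
                  config: PipelineConfig) -> list[np.ndarray]:
    """Train, align and average an embedding ensemble for every window."""
    seeds = np.random.SeedSequence(config.seed).generate_state(
        2 * len(windows)) % (2 ** 31)
    averaged = []
    for t, window in enumerate(windows):
        if window.total() > config.n_cooccurrences:
            window = subsample_pairs(window, config.n_cooccurrences,
                                     int(seeds[2 * t]))
        pairs = TrainingPairs.from_window(window, vocab)
        ensemble = train_ensemble(pairs, config.sgns,
                                  master_seed=int(seeds[2 * t + 1]),
                                  n_runs=config.n_runs, vocabulary=vocab,
                                  window_label=window.window_start_year)
        averaged.append(align_runs_and_average(
            [r.word_vectors for r in ensemble.runs]))
    return averaged


def run_pipeline(windows, vocab: Vocabulary, config: PipelineConfig,
                 fit_range: tuple[int, int] | None = None,
                 presaturation: bool = False) -> PipelineResult:
    """Full pipeline on ready-made co-occurrence windows.

    With ``presaturation`` the exponent fit is restricted to lags whose MSD
    stays below the cloud size (displacement below the cloud radius).
    """
    averaged = embed_windows(windows, vocab, config)
    labels = [w.window_start_year for w in windows]
    diachronic = chain_align_time(averaged, labels, vocab)
    if fit_range is None and presaturation:
        curve = ensemble_msd(squared_displacement(diachronic.positions))
        fit_range = presaturation_range(
            curve, cloud_size(diachronic.positions[0]))
    summary = per_word_exponents(diachronic.positions, fit_range)
    return PipelineResult(diachronic, summary,
                          summary.ensemble_fit.fit_range)
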