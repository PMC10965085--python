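"""Pipeline configuration.

One dataclass collects every tunable of the co-occurrence → embedding →
alignment → exponent pipeline.  Defaults correspond to the full-scale study
conditions (English-fiction-sized n-gram corpora): a 10-year sliding window,
a vocabulary floor of 100 occurrences per window, N_c = 10^7 co-occurrence
tokens per window, 300-dimensional skip-gram embeddings trained M = 80 times
per window, data from 1950 onwards.  Desk-scale analyses construct a config
with smaller values; the semantics are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class SGNSConfig:
    """Hyperparameters of skip-gram-with-negative-sampling training.

    The embedding objective itself fixes none of these; values are the
    community defaults for SGNS trained on co-occurrence pairs.
    """

    dim: int = 300                 # embedding dimension D
    epochs: int = 5
    negative: int = 5              # negative samples k per positive pair
    learning_rate: float = 0.025   # initial rate, linearly decayed to 1e-4
    noise_power: float = 0.75      # exponent of the negative-sampling table
    batch_size: int = 8192

    def __post_init__(self) -> None:
        if self.dim < 1 or self.epochs < 1 or self.negative < 1:
            raise ValueError("dim, epochs and negative must be positive")
        if not 0.0 < self.noise_power <= 1.0:
            raise ValueError("noise_power must lie in (0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    window_width_years: int = 10
    min_count: int = 100
    n_cooccurrences: int = 10_000_000   # N_c, subsample size per window
    context_window: int = 2             # co-occurrence distance w
    n_runs: int = 80                    # M, independent embeddings per window
    year_min: int = 1950
    seed: int = 0
    sgns: SGNSConfig = field(default_factory=SGNSConfig)

    def __post_init__(self) -> None:
        for name in ("window_width_years", "min_count", "n_cooccurrences",
                     "context_window", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def with_(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
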