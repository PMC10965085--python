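"""Full pipeline on a synthetic corpus with known latent drift.

Words move in a latent meaning space by fractional Brownian motion
(α = 0.5) and emit co-occurrence counts through a softmax of dot products;
the complete corpus → skip-gram ensemble → alignment → exponent pipeline
is then asked to detect that drift.  A drift-free (static) corpus
processed identically measures the embedding noise floor.  Sizes here are
reduced relative to the validation suite so the script runs in about a
minute.
"""

from semdrift import (LatentCorpusParams, PipelineConfig, SGNSConfig,
                      generate_latent_corpus, run_pipeline)

config = PipelineConfig(n_cooccurrences=50_000, n_runs=3, seed=1,
                        sgns=SGNSConfig(dim=30, epochs=3))

for drift in ("fbm", "static"):
    params = LatentCorpusParams(
        n_words=300, latent_dim=30, n_windows=15, drift_process=drift,
        target_alpha=0.5, pairs_per_window=50_000, seed=2)
    windows, vocab, truth = generate_latent_corpus(params)
    result = run_pipeline(windows, vocab, config)
    print(f"{drift:>6} drift: ensemble ⟨α⟩ = "
          f"{result.summary.ensemble_alpha:.3f}, "
          f"mean ᾱ = {result.summary.mean_alpha:.3f}, "
          f"fit r² = {result.summary.ensemble_fit.r_squared:.3f}")

print("\nThe drifting corpus yields a clearly positive, subdiffusive "
      "exponent; the static corpus shows only the flat noise floor of "
      "embedding + alignment stochasticity.")
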