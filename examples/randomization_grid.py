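"""Null-model grid: which temporal correlations carry subdiffusion?

Decomposes a long-memory ensemble (fBm, α = 0.4) into step sizes and
directions, randomizes each ingredient separately, and fits the
ensemble-average exponent of every reconstruction.  Reading the grid:
randomizing directions erases the memory (⟨α⟩ → 1), while keeping original
directions preserves much of it — the same diagnostic the method applies
to real word trajectories.
"""

from semdrift import FBMParams, generate_fbm, randomization_grid

trajectories = generate_fbm(
    FBMParams(target_alpha=0.4, n_times=50, dims=3, n_traj=500, seed=11))

grid = randomization_grid(trajectories, seed=11)
table = grid.pivot(index="size_mode", columns="direction_mode",
                   values="ensemble_alpha")
table = table.loc[["random", "sampled", "shuffled", "original"],
                  ["random", "shuffled", "original"]]

print("ensemble-average exponent ⟨α⟩ by randomization cell "
      "(input: fBm, α = 0.4):\n")
print(table.round(3).to_string())
print("\n(original, original) reproduces the input's memory; "
      "(random, random) is a plain random walk at ⟨α⟩ ≈ 1.")
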