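"""Does temporal alignment manufacture subdiffusion?  (It must not.)

A random walk whose cloud is held at constant total size is the null model
for the diachronic alignment pipeline: its steps carry no temporal
correlations, so after chain-aligning the per-time clouds with orthogonal
Procrustes maps the fitted exponent must stay at α ≈ 1.  A value well below
1 here would mean the smoothing itself creates spurious subdiffusion.
"""

from semdrift import generate_random_walk
from semdrift.alignment import chain_align_time, cloud_size
from semdrift.diffusion import (ensemble_msd, fit_exponent,
                                presaturation_range, squared_displacement)

walk = generate_random_walk(n_traj=500, n_times=50, dims=100,
                            constant_cloud=True, rng=42)
aligned = chain_align_time(list(walk))

curve = ensemble_msd(squared_displacement(aligned.positions))
size = cloud_size(aligned.positions[0])
fit_range = presaturation_range(curve, size)
fit = fit_exponent(curve, fit_range)

print(f"cloud size Tr V          : {size:.2f} (held constant)")
print(f"pre-saturation fit range : lags {fit_range[0]}..{fit_range[1]}")
print(f"fitted ensemble exponent : {fit.alpha:.3f} (r² = {fit.r_squared:.4f})")
print("\nα ≈ 1 confirms that maximal smoothing applied to uncorrelated "
      "motion leaves the diffusion class unchanged.")
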