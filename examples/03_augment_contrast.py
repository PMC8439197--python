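"""Generate contrast-altered variants of one volume.

Each variant shifts the tissue components' means/variances by offsets
drawn uniformly within the packaged multi-scanner ranges, then remaps
every voxel so its Mahalanobis distance to each original component is
preserved — new contrast, same anatomy.
"""

import numpy as np

from gmmda import PhantomSpec, augment, default_ranges, fit_gmm, generate_phantom

vol, _ = generate_phantom(PhantomSpec(grid_shape=(64, 64, 64), seed=7))

ranges = default_ranges()
print("perturbation half-widths s_mu =", ranges.s_mu, " s_var =", ranges.s_var)

variants = augment(vol, ranges, rng_seed=11, n_variants=3)
for i, var in enumerate(variants):
    refit, _ = fit_gmm(var.volume)
    print(f"variant {i}: q_mu = {np.round(var.perturbation.q_mu, 4)}")
    print(f"  target means  {np.round(np.sort(var.perturbed_params.mu), 4)}")
    print(f"  refit means   {np.round(refit.mu, 4)}")
# The refit means of each variant should sit on the perturbed targets:
# the augmentation really moved the tissue contrast where it was told to,
# while the underlying label geometry is untouched.
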