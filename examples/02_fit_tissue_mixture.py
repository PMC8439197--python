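"""Fit the 3-component tissue mixture and check the segmentation it implies.

The intensity histogram of a skull-stripped T1w brain has one mode per
tissue; EM recovers the mode parameters, Bayes' rule gives per-voxel class
posteriors, and the argmax map should reproduce the phantom's ground-truth
labels almost perfectly on clean data.
"""

import numpy as np

from gmmda import PhantomSpec, class_map, dice, fit_gmm, generate_phantom, posteriors

vol, truth = generate_phantom(PhantomSpec(grid_shape=(64, 64, 64), seed=7))

params, report = fit_gmm(vol)
print(f"EM converged={report.converged} after {report.n_iterations} iterations, "
      f"mean log-likelihood {report.log_likelihood:.4f}")
for name, pi, mu, var in zip(params.labels, params.pi, params.mu, params.var):
    print(f"  {name}: weight {pi:.3f}, mean {mu:.4f}, variance {var:.6f}")

post = posteriors(vol, params)
seg = class_map(post)
scores = {name: dice(seg, truth, k) for k, name in enumerate(params.labels, start=1)}
print("Dice vs ground truth:", {k: round(v, 4) for k, v in scores.items()})
# Fitted means should match the generating means (0.2/0.5/0.8) to ~1e-3
# and Dice should be ~1.0: the mixture "reads" the histogram correctly.
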