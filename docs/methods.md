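# Methods

## Model and procedure

`gmmda` treats the masked intensity histogram of a skull-stripped,
bias-field-corrected T1w brain volume as a K-component univariate
Gaussian mixture (K = 3 by default; components read CSF, GM, WM in
ascending-mean order). The augmentation pipeline is

1. **Normalization** — clip masked intensities at their 1st/99th
   percentile and map affinely to [0, 1]. Percentiles are computed over
   brain voxels only: the background zeros of a skull-stripped image
   would otherwise dominate the lower percentile.
2. **Fit** — EM on the masked intensities; the fit is cached per image
   because it does not depend on the perturbation.
3. **Perturb** — draw additive offsets for each component's mean and
   variance from uniform distributions U(−s, s) with calibrated
   half-widths, and shift the parameters. Mixing weights are untouched;
   component identity is kept even if the shifted means re-order
   (extreme but anatomically coherent contrasts are intentional).
4. **Reconstruct** — preserve each voxel's signed Mahalanobis distance
   (v − μₖ)/σₖ to every *original* component and blend the
   per-component candidates with the *original* posteriors.

Deriving both distances and blending weights from the original fit is
what makes zero perturbation an exact identity — Σₖ p(k|v)(μₖ + dᵥₖσₖ) =
v — and what guarantees that a voxel with posterior ≈ 1 for one class
keeps its within-class position under any perturbation. Re-deriving
either from the perturbed parameters would break both properties.

### Assumptions

- Input is skull-stripped (background exactly 0) and bias-field
  corrected. A residual multiplicative bias field broadens and mixes the
  per-class intensity modes, degrading the fit and hence the
  augmentation; the bias-sensitivity experiment quantifies this on
  phantoms. Bias correction (N4) and spatial registration are left to
  external tools by design.
- One intensity mode per tissue class. Pathology that overlaps a class
  (e.g. lesions near the GM mode) is not modeled separately; K is a
  parameter but no 4th-component lesion model is provided.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| K | 3 | — | CSF/GM/WM tissue classes of a T1w brain |
| s(μ) | (0.03, 0.06, 0.08) | normalized intensity | packaged reference half-widths calibrated on a large multi-scanner clinical T1w collection |
| s(σ²) | (0.001, 0.001, 0.003) | squared normalized intensity | same calibration |
| clip percentiles | 1 / 99 | % | removes extreme values before fitting |
| EM tol | 1e-4 | relative mean log-likelihood change | conventional; fits converge in ~10–30 iterations |
| EM max_iter | 200 | iterations | safety bound |
| variance floor | 1e-6 | squared normalized intensity | prevents component collapse during EM and negative variances after perturbation |
| clip output | off | — | Eq.-level reconstruction can leave [0, 1]; clamping would silently break distance preservation, so it is an explicit opt-in |

Calibration from a local image collection (`estimate_ranges`) uses the
sample (ddof = 1) standard deviation of the per-image fitted parameters,
components matched by ascending mean. Failed fits are skipped with a
warning rather than aborting a long run.

## Numerical choices

- **Posteriors in log space** with log-sum-exp normalization: voxels far
  from every component still get finite, normalized posteriors.
- **EM initialization**: the default `init="auto"` runs EM from two
  deterministic starting points — a quantile init (component k's mean at
  the (2k−1)/(2K) quantile, shared variance, uniform weights) and a
  seeded k-means init — and keeps the higher-likelihood solution. With
  narrow, well-separated clusters either single start can strand two
  components in one cluster (a classic EM local optimum; observed in
  ~12% of fits on dispersed phantom collections with quantile init
  alone). Both single inits remain selectable.
- **Convergence** when the per-voxel mean log-likelihood changes by less
  than tol relative to max(1, |previous|); the recorded trace is
  non-decreasing (tested with 1e-8 slack).
- **Negative variance policy** after perturbation: redraw the offset (up
  to 100 tries), then clamp so the perturbed variance equals the floor.
- **Tie-break** in the hard class map: lowest component index.
- **Storage** float32 (MRI convention), all internal arithmetic float64.
  `.nii.gz` is written through gzip with mtime = 0 so identical runs are
  byte-identical.
- **Sub-seeding**: variant i's seed is spawned from the master seed by
  counter, so variant i does not depend on how many variants are
  requested, and two iterators with the same seed yield identical
  streams.

## The phantom generator

The synthetic phantom emulates exactly the features the method consumes:
K nested ellipsoidal compartments (outermost CSF, innermost WM, plus a
central "ventricle" relabelled CSF so the CSF class has interior
support), per-class Gaussian intensities with strictly increasing means,
an optional low-order random-polynomial multiplicative bias field, and
optional Rician noise (|signal + complex Gaussian|, the magnitude-MRI
model). Intensities are not clipped at generation; clipping belongs to
preprocessing.

The bias field is centred and peak-scaled over the brain mask, so the
stated amplitude is what brain tissue actually experiences (polynomials
peak at the grid corners, outside any brain); it is then clamped to
[1 ± amplitude] globally and has masked mean exactly 1.

What the phantom does **not** emulate: realistic cortical morphology,
partial-volume mixing at tissue boundaries, heavy-tailed intensity
outliers (vessels, dura), pathology, or spatially correlated noise.
Passing tests on phantoms therefore validates the algebra and statistics
of the method — identity, distance preservation, parameter and
dispersion recovery — not its clinical benefit on real scans.

## Study conditions used by tests and the acceptance script

- Clean phantoms: 48³–64³ grids, means (0.2, 0.5, 0.8), SDs 0.02 —
  well-separated classes, the regime where mixture segmentation is
  near-perfect and deviations are attributable to the code under test.
- Calibration recovery: 50 phantoms at 24³, within-image SD 0.01,
  between-image class-mean offsets standardized so their sample SD is
  exactly the nominal dispersion (0.05) — the estimator is judged on
  recovery, not on the draw's sampling luck. These phantoms are already
  on a common normalized scale, so `estimate_ranges(preprocess=False)`
  is used: per-image percentile normalization would pin each image's
  darkest/brightest class near 0/1 and absorb precisely the
  between-image contrast variation being measured. For raw clinical
  collections the default `preprocess=True` path applies.
- Bias sensitivity: 32³ phantoms, amplitudes 0/0.2/0.4, 10 seeds each;
  the mean class-map Dice of an augmented-then-refit volume against
  ground truth decreases strictly with amplitude.

Problem sizes were chosen so the whole suite and the acceptance script
each run in well under a minute on a single CPU while keeping every
statistical tolerance comfortably non-trivial.

## Known limitations

- Univariate only: no multi-sequence (multivariate) mixtures.
- No spatial regularization (MRF or atlas priors) in the fit; the hard
  class map is a test instrument, not a segmentation product.
- The packaged default half-widths are a fixed reference calibration;
  cohorts with very different contrast statistics should recalibrate
  with `estimate_ranges`.
- Augmented outputs can leave [0, 1] unless clipping is requested.
- The method presumes bias-corrected input; it does not model or remove
  bias fields, and the phantom experiments show its fit degrades
  predictably when one is present.
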