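# gmmda — contrast augmentation for brain MRI via Gaussian-mixture intensity remapping

T1-weighted brain MRI contrast varies across scanners, centres and
acquisition protocols: the same brain shows different CSF/GM/WM intensity
distributions on different hardware. Segmentation models trained on one
scanner's contrast often degrade on another's. `gmmda` implements a
model-based intensity augmentation that generates realistic contrast
variants of a training image while leaving its anatomy untouched, so a
downstream model sees many "scanners" from one dataset. It is aimed at
people building MRI analysis or training pipelines in Python.

## The method

A skull-stripped, bias-corrected T1w histogram is modeled as a
3-component Gaussian mixture over voxel intensities v:

    p(v) = Σₖ πₖ N(v | μₖ, σₖ²),        k ∈ {CSF, GM, WM}

fitted per image by EM, with class posteriors from Bayes' rule

    p(C = k | v) = πₖ N(v | μₖ, σₖ²) / Σₖ' πₖ' N(v | μₖ', σₖ'²).

One augmentation draw perturbs each component by uniform offsets

    qμₖ ~ U(−s(μₖ), s(μₖ)),   qσ²ₖ ~ U(−s(σ²ₖ), s(σ²ₖ)),
    μₖ' = μₖ + qμₖ,           σₖ²' = σₖ² + qσ²ₖ,

where the half-widths s(·) are calibrated as the standard deviation of
the fitted parameters across a multi-scanner image collection (packaged
defaults: s(μ) = {3, 6, 8}×10⁻², s(σ²) = {1, 1, 3}×10⁻³ for CSF/GM/WM on
the [0, 1]-normalized scale). The new image preserves each voxel's signed
Mahalanobis distance dᵥₖ = (v − μₖ)/σₖ to every *original* component and
blends with the *original* posteriors:

    vₖ' = μₖ' + dᵥₖ σₖ',      v' = Σₖ p(C = k | v) vₖ'.

Pure-tissue voxels therefore keep their position within their class under
the new contrast (zero perturbation reproduces the input exactly); only
mixed boundary voxels blend. A seeded synthetic phantom generator (nested
CSF/GM/WM ellipsoids, optional polynomial bias field and Rician noise)
provides ground-truthed test data, so every stage is verifiable without
clinical images.

## Worked example

`examples/` contains one short script per capability. Fitting and
augmenting a 64³ phantom (`examples/02_fit_tissue_mixture.py`,
`examples/03_augment_contrast.py`) prints:

```
EM converged=True after 14 iterations, mean log-likelihood 1.4166
  CSF: weight 0.396, mean 0.2001, variance 0.000399
  GM: weight 0.359, mean 0.5001, variance 0.000398
  WM: weight 0.244, mean 0.8000, variance 0.000398
Dice vs ground truth: {'CSF': 1.0, 'GM': 1.0, 'WM': 1.0}

variant 1: q_mu = [ 0.0092  0.0439 -0.0332]
  target means  [0.0676 0.5473 0.9148]
  refit means   [0.0676 0.5473 0.9148]
```

The fitted means recover the phantom's generating means (0.2/0.5/0.8) to
~1e-4 and the hard class map reproduces the ground-truth labels (Dice
1.0). Each augmented variant, when refitted, lands exactly on the
perturbed target means — the contrast moved where it was told to while
the anatomy stayed put.

The same pipeline is available from the shell:

```bash
gmmda phantom --shape 64,64,64 --seed 7 --out img.nii.gz --labels lab.nii.gz
gmmda fit img.nii.gz --out params.json
gmmda augment img.nii.gz --defaults --seed 11 --n 3 --out-prefix aug_
```

Every output volume carries a JSON sidecar with the sampled offsets and
the fitted/perturbed parameters, sufficient to regenerate it exactly.
For training loops, `gmmda.augmenting_iterator` yields variants on the
fly with per-image fit caching.

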