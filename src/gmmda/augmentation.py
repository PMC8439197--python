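"""Contrast augmentation by Gaussian-mixture perturbation.

The core of the package. Given a skull-stripped, bias-corrected volume:

1. normalize (percentile clip, [0, 1]) and fit the K-component tissue
   mixture once;
2. draw additive offsets q_mu[k] ~ U(-s_mu[k], s_mu[k]) and
   q_var[k] ~ U(-s_var[k], s_var[k]) and shift each component:
   mu'_k = mu_k + q_mu[k], sigma^2'_k = sigma^2_k + q_var[k];
3. reconstruct a contrast-altered image that preserves per-voxel anatomy:
   each voxel's signed Mahalanobis distance d_vk = (v - mu_k) / sigma_k to
   every ORIGINAL component is kept, giving per-component candidates
   v'_k = mu'_k + d_vk * sigma'_k, which are blended with the ORIGINAL
   posteriors: v' = sum_k p(C = k | v) v'_k.

Because the posteriors and distances come from the original fit, zero
perturbation reproduces the input exactly:
sum_k p(k|v) (mu_k + d_vk sigma_k) = sum_k p(k|v) v = v. Voxels that
belong almost surely to one class keep their distance to that class under
the new parameters, so tissue structure survives arbitrary contrast
changes; only mixed boundary voxels blend. Perturbed components may
overlap or even swap order — extreme but anatomically coherent contrasts
are intentional, which is also why reconstructed intensities are not
clipped to [0, 1] by default.

Augmentation is a training-time transform: generate variants on the fly
while training a downstream model, never at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .calibration import VariationRanges
from .exceptions import GmmdaError
from .gmm import VARIANCE_FLOOR, FitReport, MixtureParams, PosteriorField, fit_gmm, posteriors
from .preprocessing import prepare_for_gmm
from .volume import IntensityVolume

__all__ = [
    "PerturbationSample",
    "sample_perturbation",
    "perturb_params",
    "mahalanobis_distances",
    "reconstruct",
    "augment",
    "augmenting_iterator",
    "AugmentedVariant",
]

#: retries when a drawn variance offset would push a variance below floor
_MAX_RESAMPLE = 100


@dataclass
class PerturbationSample:
    """One draw of per-component mean/variance offsets."""

    q_mu: np.ndarray
    q_var: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.q_mu = np.asarray(self.q_mu, dtype=np.float64)
        self.q_var = np.asarray(self.q_var, dtype=np.float64)

    def to_json(self) -> dict:
        return {
            "q_mu": self.q_mu.tolist(),
            "q_var": self.q_var.tolist(),
            "seed": int(self.seed),
        }


def _as_seed_int(seed: int | np.random.SeedSequence) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
    return int(seed)


def sample_perturbation(
    ranges: VariationRanges,
    params: MixtureParams,
    rng_seed: int | np.random.SeedSequence = 0,
) -> PerturbationSample:
    """Draw q_mu[k] ~ U(-s_mu[k], s_mu[k]) and q_var[k] ~ U(-s_var[k], s_var[k]).

    A variance offset that would push component k's variance below the
    floor is redrawn (up to 100 tries) and finally clamped so that
    sigma^2_k + q_var[k] == floor. Deterministic given the seed.
    """
    if ranges.K != params.K:
        raise GmmdaError(f"ranges have K={ranges.K} but params have K={params.K}")
    seed_int = _as_seed_int(rng_seed)
    rng = np.random.default_rng(seed_int)
    q_mu = np.array([rng.uniform(-s, s) if s > 0 else 0.0 for s in ranges.s_mu])
    q_var = np.empty(params.K)
    for k, s in enumerate(ranges.s_var):
        if s == 0:
            q_var[k] = 0.0
            continue
        draw = rng.uniform(-s, s)
        for _ in range(_MAX_RESAMPLE):
            if params.var[k] + draw >= VARIANCE_FLOOR:
                break
            draw = rng.uniform(-s, s)
        else:
            draw = VARIANCE_FLOOR - params.var[k]
        q_var[k] = draw
    return PerturbationSample(q_mu=q_mu, q_var=q_var, seed=seed_int)


def perturb_params(params: MixtureParams, q: PerturbationSample) -> MixtureParams:
    """Shift each component's mean and variance by the sampled offsets.

    Mixing coefficients are unchanged and component identity (index) is
    preserved even if the shifted means re-order; variances are floored.
    """
    if q.q_mu.size != params.K:
        raise GmmdaError("perturbation size does not match component count")
    return MixtureParams(
        pi=params.pi.copy(),
        mu=params.mu + q.q_mu,
        var=np.maximum(params.var + q.q_var, VARIANCE_FLOOR),
        labels=params.labels,
    )


def mahalanobis_distances(vol: IntensityVolume, params: MixtureParams) -> np.ndarray:
    """Signed per-voxel, per-component distances (v - mu_k) / sigma_k.

    Shape (n_masked, K). Undefined (and rejected) if any sigma_k is 0.
    """
    sigma = params.sigma
    if np.any(sigma <= 0):
        raise GmmdaError("Mahalanobis distance undefined for zero-variance component")
    return (vol.masked_values[:, None] - params.mu) / sigma


def reconstruct(
    vol: IntensityVolume,
    params: MixtureParams,
    new_params: MixtureParams,
    post: PosteriorField,
    clip: bool = False,
) -> IntensityVolume:
    """Rebuild the image under new component parameters.

    ``post`` must be the posterior field of ``vol`` under ``params`` (the
    original fit): distances and blending weights both derive from the
    original parameters. Background is untouched. ``clip`` optionally
    clamps the output to [0, 1]; off by default because clamping breaks
    the exact distance-preservation property.
    """
    if params.K != new_params.K or post.K != params.K:
        raise GmmdaError("component counts of params, new_params and post must agree")
    if post.mask.shape != vol.mask.shape or not np.array_equal(post.mask, vol.mask):
        raise GmmdaError("posterior field mask does not match the volume mask")
    d = mahalanobis_distances(vol, params)
    candidates = new_params.mu + d * new_params.sigma
    blended = (post.probs * candidates).sum(axis=1)
    if clip:
        blended = np.clip(blended, 0.0, 1.0)
    out = np.zeros_like(vol.data)
    out[vol.mask] = blended
    return IntensityVolume(out, mask=vol.mask.copy(), affine=vol.affine.copy())


@dataclass
class AugmentedVariant:
    """One augmented image plus the provenance to regenerate it exactly."""

    volume: IntensityVolume
    perturbation: PerturbationSample
    fitted_params: MixtureParams
    perturbed_params: MixtureParams

    def provenance(self) -> dict:
        return {
            "perturbation": self.perturbation.to_json(),
            "fitted_params": self.fitted_params.to_json(),
            "perturbed_params": self.perturbed_params.to_json(),
        }

    def write_provenance(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.provenance(), indent=2) + "\n")


@dataclass
class _FittedVolume:
    """Cached per-volume pipeline state: one fit serves every variant."""

    prepared: IntensityVolume
    params: MixtureParams
    report: FitReport
    post: PosteriorField


def _fit_pipeline(vol: IntensityVolume, K: int, **fit_kwargs) -> _FittedVolume:
    prepared = prepare_for_gmm(vol)
    params, report = fit_gmm(prepared, K=K, **fit_kwargs)
    post = posteriors(prepared, params)
    return _FittedVolume(prepared, params, report, post)


def _one_variant(
    fitted: _FittedVolume,
    ranges: VariationRanges,
    seed: int | np.random.SeedSequence,
    clip: bool,
) -> AugmentedVariant:
    q = sample_perturbation(ranges, fitted.params, seed)
    new_params = perturb_params(fitted.params, q)
    out = reconstruct(fitted.prepared, fitted.params, new_params, fitted.post, clip=clip)
    return AugmentedVariant(out, q, fitted.params, new_params)


def augment(
    vol: IntensityVolume,
    ranges: VariationRanges,
    K: int = 3,
    rng_seed: int = 0,
    n_variants: int = 1,
    clip: bool = False,
    **fit_kwargs,
) -> list[AugmentedVariant]:
    """Full pipeline: normalize, fit once, reconstruct ``n_variants`` images.

    Per-variant seeds are spawned from the master seed by counter, so
    variant i is the same regardless of ``n_variants``. The input is
    assumed skull-stripped and bias-field corrected.
    """
    fitted = _fit_pipeline(vol, K, **fit_kwargs)
    children = np.random.SeedSequence(rng_seed).spawn(n_variants)
    return [_one_variant(fitted, ranges, child, clip) for child in children]


def augmenting_iterator(
    volumes: Sequence[IntensityVolume],
    ranges: VariationRanges,
    rng_seed: int = 0,
    K: int = 3,
    clip: bool = False,
    **fit_kwargs,
) -> Iterator[AugmentedVariant]:
    """Lazily yield fresh augmented variants, cycling through ``volumes``.

    Intended as a drop-in on-the-fly augmentation stream for training
    pipelines. Each source volume is normalized and fitted exactly once
    (cached); every yielded variant uses a fresh counter-derived sub-seed,
    so two iterators built with the same seed produce identical streams.
    An empty volume sequence yields an empty stream.
    """
    if len(volumes) == 0:
        return
    cache: dict[int, _FittedVolume] = {}
    ss = np.random.SeedSequence(rng_seed)
    i = 0
    while True:
        idx = i % len(volumes)
        if idx not in cache:
            cache[idx] = _fit_pipeline(volumes[idx], K, **fit_kwargs)
        child = ss.spawn(1)[0]
        yield _one_variant(cache[idx], ranges, child, clip)
        i += 1
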