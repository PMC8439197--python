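"""Seeded synthetic brain-like phantoms with known tissue parameters.

The phantom stands in for real T1-weighted scans in every test: K nested
ellipsoidal compartments (outermost = CSF, innermost = WM for the usual
K = 3) plus a small interior "ventricle" ellipsoid relabelled CSF, so each
tissue class is present with a controllable volume fraction. Each voxel of
class k draws its intensity from Normal(class_means[k], class_stds[k]^2);
the volume may then be corrupted by a smooth multiplicative bias field and
Rician noise — the two dominant intensity artifacts of magnitude MRI.

Intensities are deliberately NOT clipped to [0, 1] at generation time:
clipping is a preprocessing concern and happens in
:func:`gmmda.preprocessing.prepare_for_gmm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import GmmdaError, InvalidGeometryError
from .volume import IntensityVolume, LabeledVolume

__all__ = ["PhantomSpec", "generate_phantom", "generate_bias_field", "rician_noise"]

#: default nested-shell outer radii as fractions of the half grid extent,
#: outermost (CSF) first; the innermost entry bounds the WM core
DEFAULT_SHELL_FRACTIONS = (0.92, 0.78, 0.58)
#: radius fraction of the interior ventricle (labelled CSF)
DEFAULT_VENTRICLE_FRACTION = 0.18


@dataclass
class PhantomSpec:
    """Full description of a synthetic phantom.

    Attributes
    ----------
    grid_shape : (int, int, int)
        Lattice size in voxels.
    class_means, class_stds : sequence of float
        True per-class intensity mean and standard deviation, ordered by
        class label 1..K; means must be strictly increasing (CSF < GM < WM).
    shell_fractions : sequence of float
        Outer radius of each nested ellipsoid as a fraction of the half
        extent, strictly decreasing, one per class.
    ventricle_fraction : float
        Radius fraction of the central ellipsoid relabelled class 1 (CSF);
        0 disables it.
    bias_order, bias_amplitude : int, float
        Bias-field polynomial order and peak fractional deviation;
        amplitude 0 disables the field.
    noise_sigma : float
        Rician noise level in intensity units; 0 disables noise.
    seed : int
        Master seed; identical specs with identical seeds generate
        bit-identical volumes.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    class_means: tuple[float, ...] = (0.2, 0.5, 0.8)
    class_stds: tuple[float, ...] = (0.02, 0.02, 0.02)
    shell_fractions: tuple[float, ...] = DEFAULT_SHELL_FRACTIONS
    ventricle_fraction: float = DEFAULT_VENTRICLE_FRACTION
    bias_order: int = 2
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.class_means = tuple(float(m) for m in self.class_means)
        self.class_stds = tuple(float(s) for s in self.class_stds)
        self.shell_fractions = tuple(float(f) for f in self.shell_fractions)
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise GmmdaError(f"grid_shape must be a positive triple: {self.grid_shape}")
        k = len(self.class_means)
        if len(self.class_stds) != k or len(self.shell_fractions) != k:
            raise GmmdaError("class_means, class_stds and shell_fractions must share length K")
        if any(b <= a for a, b in zip(self.class_means, self.class_means[1:])):
            raise GmmdaError("class_means must be strictly increasing (CSF < GM < WM)")
        if any(s <= 0 for s in self.class_stds):
            raise GmmdaError("class_stds must all be > 0")
        if any(b >= a for a, b in zip(self.shell_fractions, self.shell_fractions[1:])):
            raise GmmdaError("shell_fractions must be strictly decreasing")
        if not 0 < self.shell_fractions[0] <= 1:
            raise GmmdaError("outermost shell fraction must lie in (0, 1]")
        if self.ventricle_fraction < 0 or self.ventricle_fraction >= self.shell_fractions[-1]:
            raise GmmdaError("ventricle_fraction must lie in [0, innermost shell fraction)")
        if not 0 <= self.bias_amplitude < 1:
            raise GmmdaError("bias_amplitude must lie in [0, 1)")
        if self.bias_order < 1:
            raise GmmdaError("bias_order must be >= 1")
        if self.noise_sigma < 0:
            raise GmmdaError("noise_sigma must be >= 0")

    @property
    def n_classes(self) -> int:
        return len(self.class_means)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "class_means": list(self.class_means),
            "class_stds": list(self.class_stds),
            "shell_fractions": list(self.shell_fractions),
            "ventricle_fraction": self.ventricle_fraction,
            "bias_order": self.bias_order,
            "bias_amplitude": self.bias_amplitude,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _normalized_radius(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal radius of each voxel, 1.0 at the bounding half extent."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) / ((n - 1) / 2.0 if n > 1 else 1.0)
        for n in grid_shape
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(xx**2 + yy**2 + zz**2)


def _build_labels(spec: PhantomSpec) -> np.ndarray:
    r = _normalized_radius(spec.grid_shape)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    # fill outside-in: outermost shell = class 1 (CSF), core = class K (WM)
    for k, frac in enumerate(spec.shell_fractions, start=1):
        labels[r <= frac] = k
    if spec.ventricle_fraction > 0:
        labels[r <= spec.ventricle_fraction] = 1
    counts = np.bincount(labels.ravel(), minlength=spec.n_classes + 1)
    missing = [k for k in range(1, spec.n_classes + 1) if counts[k] == 0]
    if missing:
        raise InvalidGeometryError(
            f"grid {spec.grid_shape} too small: classes {missing} have no voxels"
        )
    return labels


def generate_bias_field(
    grid_shape: tuple[int, int, int],
    order: int,
    amplitude: float,
    seed: int | np.random.Generator = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """A smooth multiplicative intensity-inhomogeneity field.

    A random polynomial of total degree <= ``order`` over coordinates
    normalized to [-1, 1] is centred to zero mean and rescaled so its peak
    deviation equals ``amplitude``; the returned field is ``1 + that
    surface``, hence mean exactly 1 and values in [1-amplitude,
    1+amplitude]. This emulates the spatially smooth low-frequency gain
    variation of uncorrected MRI.

    When ``mask`` is given, centring and peak-scaling are computed over
    the masked region, so the stated amplitude is realized *inside the
    brain* rather than at the grid corners where polynomials peak; the
    field is then clamped to [1-amplitude, 1+amplitude] globally (the
    clamp can only touch voxels outside the mask).
    """
    if order < 1:
        raise GmmdaError("bias field order must be >= 1")
    if not 0 <= amplitude < 1:
        raise GmmdaError(
            "bias amplitude must lie in [0, 1): amplitude >= 1 would allow "
            "non-positive intensities"
        )
    grid_shape = tuple(int(s) for s in grid_shape)
    if amplitude == 0:
        return np.ones(grid_shape, dtype=np.float64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axes = [
        (np.arange(n) - (n - 1) / 2.0) / ((n - 1) / 2.0 if n > 1 else 1.0)
        for n in grid_shape
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    g = np.zeros(grid_shape, dtype=np.float64)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if i == j == k == 0:
                    continue  # constant term carries no spatial variation
                g += rng.normal() * xx**i * yy**j * zz**k
    region = np.ones(grid_shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    g -= g[region].mean()
    peak = np.abs(g[region]).max()
    if peak > 0:
        g *= amplitude / peak
    return np.clip(1.0 + g, 1.0 - amplitude, 1.0 + amplitude)


def rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Magnitude-MRI noise: |signal + n1 + i*n2| with n1, n2 ~ N(0, sigma)."""
    if sigma == 0:
        return signal
    real = signal + rng.normal(0.0, sigma, size=signal.shape)
    imag = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt(real**2 + imag**2)


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabeledVolume]:
    """Generate a phantom and its ground-truth labels.

    Per-voxel intensities are Gaussian around the class mean, then
    multiplied by the bias field (if enabled) and passed through Rician
    noise (if enabled), in that order — gain inhomogeneity acts on the
    signal before the acquisition noise does. Background voxels stay
    exactly 0. Identical ``(spec, seed)`` gives bit-identical output.
    """
    labels = _build_labels(spec)
    mask = labels > 0
    ss = np.random.SeedSequence(spec.seed)
    intensity_rng, bias_rng, noise_rng = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    data = np.zeros(spec.grid_shape, dtype=np.float64)
    means = np.array((0.0,) + spec.class_means)
    stds = np.array((0.0,) + spec.class_stds)
    noise = intensity_rng.standard_normal(spec.grid_shape)
    data[mask] = means[labels[mask]] + stds[labels[mask]] * noise[mask]

    if spec.bias_amplitude > 0:
        field = generate_bias_field(
            spec.grid_shape, spec.bias_order, spec.bias_amplitude, bias_rng, mask=mask
        )
        data[mask] *= field[mask]
    if spec.noise_sigma > 0:
        data[mask] = rician_noise(data[mask], spec.noise_sigma, noise_rng)

    vol = IntensityVolume(data, mask=mask)
    return vol, LabeledVolume(labels)
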