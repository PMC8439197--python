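"""Intensity normalizations applied before mixture fitting or training.

Two standard transforms for skull-stripped, bias-corrected brain MRI:

* :func:`prepare_for_gmm` — clip at the 1st/99th percentile of the masked
  intensities and map affinely to [0, 1]; the canonical preparation before
  fitting the tissue mixture.
* :func:`robust_zscore` — outlier-robust standardization: subtract the
  masked median and divide by the standard deviation of the masked values
  restricted to the 10th–90th percentile band.

All statistics are computed over masked voxels only (background zeros
would otherwise dominate the low percentiles); the mask itself is never
modified, and background voxels stay 0. Both transforms are monotone
non-decreasing on the mask, so intensity rank order is preserved.

Bias-field correction (e.g. N4) and spatial registration are deliberately
out of scope: this library expects bias-corrected input and documents that
assumption.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateInputError
from .volume import IntensityVolume

__all__ = ["prepare_for_gmm", "robust_zscore"]


def _require_mask(vol: IntensityVolume) -> np.ndarray:
    vals = vol.masked_values
    if vals.size == 0:
        raise DegenerateInputError("empty brain mask")
    if not np.all(np.isfinite(vals)):
        raise DegenerateInputError("non-finite intensities inside the mask")
    return vals


def prepare_for_gmm(
    vol: IntensityVolume, low_pct: float = 1.0, high_pct: float = 99.0
) -> IntensityVolume:
    """Percentile-clip masked intensities and rescale to [0, 1].

    Values below the ``low_pct`` percentile (of masked voxels, linear
    interpolation) map to 0, values above ``high_pct`` map to 1, and the
    band in between is mapped affinely. Background is untouched.

    Raises
    ------
    DegenerateInputError
        If the two percentiles coincide (constant image).
    """
    if not low_pct < high_pct:
        raise ValueError(f"low_pct ({low_pct}) must be < high_pct ({high_pct})")
    vals = _require_mask(vol)
    p_low, p_high = np.percentile(vals, [low_pct, high_pct])
    if p_high <= p_low:
        raise DegenerateInputError(
            f"degenerate intensity distribution: P{low_pct} == P{high_pct} == {p_low}"
        )
    scaled = (np.clip(vol.data, p_low, p_high) - p_low) / (p_high - p_low)
    return vol.with_data(scaled)


def robust_zscore(vol: IntensityVolume, trim_low: float = 10.0, trim_high: float = 90.0) -> IntensityVolume:
    """Median/trimmed-std standardization robust against outliers.

    Output is ``(v - median) / sd`` where the median is over all masked
    voxels and ``sd`` is the (population) standard deviation of masked
    values inside the [P10, P90] percentile band. Background remains 0.

    Raises
    ------
    DegenerateInputError
        If the trimmed standard deviation is zero.
    """
    vals = _require_mask(vol)
    med = np.median(vals)
    p_lo, p_hi = np.percentile(vals, [trim_low, trim_high])
    trimmed = vals[(vals >= p_lo) & (vals <= p_hi)]
    sd = float(np.std(trimmed))
    if sd == 0.0 or trimmed.size < 2:
        raise DegenerateInputError("zero trimmed standard deviation: degenerate input")
    return vol.with_data((vol.data - med) / sd)
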