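"""In-memory containers for 3-D brain volumes and their NIfTI-1 I/O.

The package operates on skull-stripped scalar volumes: every voxel outside
the brain mask is exactly zero, mirroring the convention of skull-stripped
T1-weighted MRI. If no explicit mask is given, the mask defaults to
``data > 0``.

Volumes are stored as float32 on disk (the MRI convention) and promoted to
float64 for all internal arithmetic.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import DimensionalityError, FormatError

__all__ = [
    "IntensityVolume",
    "LabeledVolume",
    "read_volume",
    "read_labels",
    "write_volume",
    "write_labels",
]


@dataclass
class IntensityVolume:
    """A 3-D scalar intensity lattice with a boolean brain mask.

    Parameters
    ----------
    data : ndarray
        3-D float array of voxel intensities. Voxels outside ``mask``
        must be 0.
    mask : ndarray of bool, optional
        True where the voxel belongs to the brain. Defaults to
        ``data > 0`` (skull-stripped convention).
    affine : (4, 4) ndarray, optional
        Voxel-to-world transform; identity by default.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got {self.data.ndim}-D with shape "
                f"{self.data.shape}"
            )
        if self.mask is None:
            self.mask = self.data > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise DimensionalityError(
                f"mask shape {self.mask.shape} != data shape {self.data.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def masked_values(self) -> np.ndarray:
        """1-D array of intensities inside the mask."""
        return self.data[self.mask]

    def with_data(self, new_data: np.ndarray) -> "IntensityVolume":
        """A copy of this volume carrying ``new_data`` but the same mask
        and affine; voxels outside the mask are forced to 0."""
        out = np.zeros_like(self.data)
        out[self.mask] = np.asarray(new_data, dtype=np.float64)[self.mask]
        return IntensityVolume(out, mask=self.mask.copy(), affine=self.affine.copy())


@dataclass
class LabeledVolume:
    """A 3-D integer label lattice: 0 = background, 1..K = tissue class."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D label volume, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("label volume contains non-integer values")
            arr = np.round(arr).astype(np.int32)
        if arr.min() < 0:
            raise FormatError("label volume contains negative values")
        self.labels = arr.astype(np.int32)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"{path}: not a readable NIfTI file ({exc})") from exc
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
    if len(img.shape) != 3:
        raise DimensionalityError(
            f"{path}: expected 3-D scalar volume, got shape {img.shape}"
        )
    return img


def read_volume(path: str | Path, mask_path: str | Path | None = None) -> IntensityVolume:
    """Read a 3-D NIfTI-1 intensity volume.

    Without ``mask_path`` the brain mask defaults to strictly positive
    voxels (skull-stripped input convention).
    """
    img = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: volume contains non-finite values")
    mask = None
    if mask_path is not None:
        mimg = _load_nifti(mask_path)
        if mimg.shape != img.shape:
            raise DimensionalityError(
                f"mask shape {mimg.shape} != volume shape {img.shape}"
            )
        mask = np.asarray(mimg.dataobj) > 0
        data = np.where(mask, data, 0.0)
    return IntensityVolume(data, mask=mask, affine=np.asarray(img.affine))


def read_labels(path: str | Path) -> LabeledVolume:
    """Read a NIfTI label volume; non-integer voxel values are rejected."""
    img = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=np.float64)
    if not np.allclose(data, np.round(data)):
        raise FormatError(
            f"{path}: label volume contains non-integer values and cannot "
            "be interpreted as a LabeledVolume"
        )
    return LabeledVolume(np.round(data).astype(np.int32), affine=np.asarray(img.affine))


def _write_nifti(img: nib.Nifti1Image, path: Path) -> None:
    # Byte-identical reruns: route .gz through gzip.compress with mtime=0
    # so no timestamp leaks into the output.
    raw = img.to_bytes()
    if path.name.endswith(".gz"):
        path.write_bytes(gzip.compress(raw, compresslevel=1, mtime=0))
    else:
        path.write_bytes(raw)


def write_volume(
    vol: IntensityVolume,
    path: str | Path,
    template_header: nib.Nifti1Header | None = None,
) -> None:
    """Write an intensity volume as float32 NIfTI-1 (.nii or .nii.gz)."""
    img = nib.Nifti1Image(
        vol.data.astype(np.float32), vol.affine, header=template_header
    )
    img.set_data_dtype(np.float32)
    _write_nifti(img, Path(path))


def write_labels(lab: LabeledVolume, path: str | Path) -> None:
    """Write a label volume as int16 NIfTI-1."""
    img = nib.Nifti1Image(lab.labels.astype(np.int16), lab.affine)
    img.set_data_dtype(np.int16)
    _write_nifti(img, Path(path))
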