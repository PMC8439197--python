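import numpy as np
import pytest

from gmmda import IntensityVolume, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_spec():
    """Well-separated three-class phantom, no bias field, no Rician noise."""
    return PhantomSpec(
        grid_shape=(48, 48, 48),
        class_means=(0.2, 0.5, 0.8),
        class_stds=(0.02, 0.02, 0.02),
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return generate_phantom(clean_spec)


def volume_from_values(values, shape=None):
    """Pack a 1-D list of masked intensities into a cubic volume whose mask
    covers exactly those voxels (remaining voxels are background)."""
    values = np.asarray(values, dtype=np.float64)
    if shape is None:
        side = int(np.ceil(values.size ** (1 / 3)))
        shape = (side, side, side)
    data = np.zeros(int(np.prod(shape)))
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    data[: values.size] = values
    mask[: values.size] = True
    return IntensityVolume(data.reshape(shape), mask=mask.reshape(shape))
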