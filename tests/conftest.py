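import numpy as np
import pytest

from multipath25d.volume_io import BrainVolume, LesionMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A small brain-like volume: nonzero ellipsoidal core, zero background."""
    shape = (16, 32, 16)
    xs = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    center = [(s - 1) / 2 for s in shape]
    radii = [0.45 * s for s in shape]
    support = sum(((x - c) / r) ** 2 for x, c, r in zip(xs, center, radii)) <= 1
    data = np.where(support, 1.0 + 0.1 * rng.standard_normal(shape), 0.0)
    return BrainVolume(data=data.astype(np.float32), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def small_mask(small_volume, rng):
    data = np.zeros(small_volume.shape, dtype=np.uint8)
    data[6:10, 12:20, 4:8] = 1
    return LesionMask(data=data, spacing=small_volume.spacing)


def write_nifti(path, data, spacing=(1.0, 1.0, 1.0)):
    """Write canonical-order array data to a NIfTI file for IO tests."""
    import nibabel as nib

    ras = np.transpose(np.asarray(data), (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(ras, affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))
    return path
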