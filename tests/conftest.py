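import numpy as np
import pytest

from petquant import ActivityVolume, GridSpec, ScannerPreset


@pytest.fixture
def identity_preset():
    """Effectively blur-free, noise-free scanner (raw-kernel semantics)."""
    return ScannerPreset(name="identity", psf_fwhm=1e-3,
                         positron_range_fwhm={"F18": 0.0, "Ga68": 0.0})


@pytest.fixture
def mild_preset():
    """A modest raw 1.5 mm Gaussian PSF without positron range or noise."""
    return ScannerPreset(name="mild", psf_fwhm=1.5,
                         positron_range_fwhm={"F18": 0.0, "Ga68": 0.0})


def make_uniform_volume(value=100.0, n=24, voxel=1.0):
    grid = GridSpec.centred((n * voxel,) * 3, (voxel,) * 3)
    return ActivityVolume(values=np.full(grid.shape, float(value)), grid=grid)


@pytest.fixture
def uniform_volume():
    return make_uniform_volume()
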