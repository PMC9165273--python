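import numpy as np
import pytest

from thyropet import phantom
from thyropet.volumes import ImageVolume, VoiMask


@pytest.fixture
def plateau_phantom():
    """Noiseless, unblurred 25 mm plateau nodule at 10 g/mL over 2 g/mL."""
    spec = phantom.NoduleSpec(
        centre_mm=[60.0, 40.0, 40.0],
        diameters_mm=[25.0, 25.0, 25.0],
        peak_suv=10.0,
        background_suv=2.0,
        texture_amplitude=0.0,
        psf_fwhm_mm=0.0,
        noise_sd_fraction=0.0,
    )
    pet, ct, truth = phantom.generate_phantom(spec, 3.18, (32, 26, 26), seed=1)
    return spec, pet, ct, truth


@pytest.fixture
def random_volume_and_mask():
    rng = np.random.default_rng(42)
    data = rng.uniform(0.5, 12.0, size=(14, 12, 10))
    vol = ImageVolume(data, spacing=[3.0, 3.0, 3.0])
    mask = np.zeros(data.shape, dtype=bool)
    mask[4:9, 3:8, 2:7] = rng.random((5, 5, 5)) > 0.4
    return vol, VoiMask(mask, vol.spacing)
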