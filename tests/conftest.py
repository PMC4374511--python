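import numpy as np
import pytest

from punctakit.profiles import IntensityProfile
from punctakit.synthetic import get_preset


def profile_from(values, spacing=1.0, mask=None):
    """Build an IntensityProfile from raw intensity values."""
    values = np.asarray(values, dtype=float)
    return IntensityProfile(
        positions_um=np.arange(values.size) * spacing,
        intensities=values,
        pixel_size_um=spacing,
        exclude_mask=mask,
    )


def bump_profile(length_um, spacing, baseline, centers, heights, sigmas):
    """Noiseless profile with Gaussian bumps on a flat baseline."""
    x = np.arange(int(round(length_um / spacing)) + 1) * spacing
    y = np.full(x.size, float(baseline))
    for c, h, s in zip(centers, heights, sigmas):
        y += h * np.exp(-((x - c) ** 2) / (2.0 * s**2))
    return IntensityProfile(positions_um=x, intensities=y, pixel_size_um=spacing)


@pytest.fixture(scope="session")
def wild_type():
    return get_preset("wild_type")


@pytest.fixture(scope="session")
def diffuse_mutant():
    return get_preset("diffuse_mutant")


@pytest.fixture(scope="session")
def enlarged_puncta():
    return get_preset("enlarged_puncta")


@pytest.fixture(scope="session")
def soma_retention():
    return get_preset("soma_retention")
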