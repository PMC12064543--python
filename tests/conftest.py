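"""Shared fixtures: small phantoms and survival fixtures, all seeded."""

import numpy as np
import pytest

from ithrad.containers import ImageVolume, ROIMask
from ithrad.synthetic import PhantomSpec, TextureParams, generate_texture_phantom


@pytest.fixture(scope="session")
def sharp_two_habitat():
    """Two compact habitats with strongly separated textures (means 0/100)."""
    spec = PhantomSpec(
        grid_shape=(32, 32),
        n_habitats=2,
        habitat_fragments=(1, 1),
        area_fractions=(0.5, 0.5),
        texture_params=(TextureParams(0.0, 1.0, 1.0), TextureParams(100.0, 1.0, 1.0)),
        seed=3,
    )
    return generate_texture_phantom(spec)


@pytest.fixture(scope="session")
def default_two_habitat():
    """Two habitats at the generator's default texture contrast."""
    spec = PhantomSpec(
        grid_shape=(32, 32),
        n_habitats=2,
        habitat_fragments=(1, 2),
        area_fractions=(0.6, 0.4),
        seed=3,
    )
    return generate_texture_phantom(spec)


@pytest.fixture()
def disk_mask_20():
    rr, cc = np.mgrid[:20, :20]
    return ROIMask((rr - 9.5) ** 2 + (cc - 9.5) ** 2 <= 8.0**2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_image(arr, spacing=None):
    return ImageVolume(np.asarray(arr, dtype=float), spacing)
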