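import numpy as np
import pytest

from petldm.core import CT_HU, PET_SUV, Mask3D, Volume3D
from petldm.phantom import PhantomSpec


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    """Toy-scale noiseless phantom conditions shared across tests."""
    return PhantomSpec(grid_shape=(32, 32, 16), spacing=(6.0, 6.0, 6.0),
                       ct_noise_sd=0.0, pet_noise_sd=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_volume(values, spacing=(1.0, 1.0, 1.0), modality=PET_SUV) -> Volume3D:
    return Volume3D(np.asarray(values, dtype=float), spacing, "RAS", modality)


def make_mask(values, spacing=(1.0, 1.0, 1.0)) -> Mask3D:
    return Mask3D(np.asarray(values) > 0, spacing, "RAS")
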