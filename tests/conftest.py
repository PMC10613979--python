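import numpy as np
import pytest

from hsin.hsi_io import Hypercube
from hsin.synth import (
    SceneSpec,
    default_profiles,
    default_swir_wavelengths,
    default_vnir_wavelengths,
    generate_dataset,
    generate_scene,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def quiet_profiles():
    return {k: p.quiet() for k, p in default_profiles().items()}


@pytest.fixture(scope="session")
def small_scene_spec():
    """64x64 scenes on the default 155+68 band grids."""
    return SceneSpec(height=64, width=64)


@pytest.fixture(scope="session")
def coarse_scene_spec():
    """Coarse grids (holding the segmentation wavelengths) for fast tests."""
    return SceneSpec(
        height=64,
        width=64,
        vnir_wavelengths=np.linspace(405.0, 1005.0, 31),  # 20 nm; includes 705/745
        swir_wavelengths=np.linspace(1040.0, 2500.0, 14),
    )


@pytest.fixture(scope="session")
def noisy_scene(small_scene_spec, profiles):
    return generate_scene(
        small_scene_spec, profiles["HNHP"], rng=np.random.default_rng(7),
        scene_id="noisy-0",
    )


@pytest.fixture(scope="session")
def quiet_scene(small_scene_spec, quiet_profiles):
    return generate_scene(
        small_scene_spec, quiet_profiles["LNHP"], rng=np.random.default_rng(8),
        scene_id="quiet-0",
    )


@pytest.fixture
def tiny_cube(rng):
    data = rng.random((4, 4, 3))
    return Hypercube(data, np.array([500.0, 510.0, 520.0]), sensor="VNIR")


@pytest.fixture(scope="session")
def tiny_dataset(coarse_scene_spec):
    return generate_dataset(2, coarse_scene_spec, seed=11)
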