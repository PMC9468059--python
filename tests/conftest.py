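import numpy as np
import pytest

from tau3dquant.phantom import PhantomConfig, make_phantom, make_region_masks


@pytest.fixture(scope="session")
def small_config():
    """Coarse, fast phantom configuration used across modules."""
    return PhantomConfig(
        grid_shape=(128, 64, 64),
        voxel_size_um=(8.0, 8.0, 8.0),
        core_radius_um=120.0,
        core_length_um=700.0,
        region_counts={"core": 120, "shell": 10, "A4": 5, "subcoeruleus": 8},
        at8_fraction=0.5,
        dorsal_bias=0.7,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_masks(small_config):
    return make_region_masks(small_config)


@pytest.fixture(scope="session")
def detection_phantom():
    """Phantom sized for detection-quality checks: 200 well-separated somas,
    high SNR, all pathological (so soma/process truth is rich)."""
    config = PhantomConfig(
        grid_shape=(256, 128, 128),
        voxel_size_um=(4.0, 4.0, 4.0),
        core_radius_um=200.0,
        core_length_um=900.0,
        region_counts={"core": 200, "shell": 0, "A4": 0, "subcoeruleus": 0},
        at8_fraction=0.5,
        at8_mode="CSR",
        dorsal_bias=0.7,
        duo_rate=0.0,
        seed=5,
    )
    return config, make_phantom(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_nn(points: np.ndarray) -> np.ndarray:
    """All-pairs nearest-neighbour oracle used by several test modules."""
    from scipy.spatial.distance import cdist

    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)
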