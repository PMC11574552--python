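import numpy as np
import pytest

from rhizokde import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_config() -> SceneConfig:
    """One full-size (3.2×3.2 mm, 6.21 µm/px) noiseless tile configuration."""
    return SceneConfig(n_roots=1)


@pytest.fixture(scope="session")
def scene(default_config):
    """A seeded full-size single-tile scene shared by read-only tests."""
    return generate_scene(default_config, root_id=0, timepoint_h=24.0, seed=11)


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """A 1.6×1.6 mm tile config for fast cohort-level tests."""
    return SceneConfig(tile_width_mm=1.6, tile_height_mm=1.6, n_roots=2,
                       tiles_per_root_range=(2, 2), timepoints_h=(12.0, 48.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
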