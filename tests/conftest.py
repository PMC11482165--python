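import numpy as np
import pytest

from octa.core_io import BScanBlock, OCTVolume
from octa.phantom import PhantomSpec, Vessel, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_block(rng):
    """A 10-frame 24x20 block of positive random intensities."""
    return BScanBlock(frames=rng.random((10, 24, 20)) + 0.01, y_index=3)


@pytest.fixture
def small_volume(rng):
    blocks = [BScanBlock(frames=rng.random((10, 16, 12)), y_index=y) for y in range(3)]
    return OCTVolume(blocks=blocks, metadata={"intensity_scale": "linear"})


def small_phantom_spec(seed=0, **overrides):
    """Desk-scale phantom: 64x64, shallow surface, three dermal vessels."""
    kwargs = dict(
        height_px=64,
        width_px=64,
        n_frames=10,
        n_y_locations=12,
        vessel_list=(
            Vessel(center_z=4 + 18, center_x=18, radius_px=5, rho=0.15),
            Vessel(center_z=4 + 32, center_x=46, radius_px=6, rho=0.30),
            Vessel(center_z=4 + 45, center_x=32, radius_px=4, rho=0.10),
        ),
        static_rho=0.95,
        attenuation_per_px=0.01,
        noise_floor=0.05,
        surface_z=4,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture
def small_phantom():
    return generate_phantom(small_phantom_spec(seed=11))
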