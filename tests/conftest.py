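import numpy as np
import pytest

from weedsynth import fixtures as fx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def soil_background():
    return fx.make_background(256, seed=1)


@pytest.fixture(scope="session")
def broadleaf():
    inst, mask = fx.make_instance(fx.FixtureSpec(archetype="broadleaf", size=64, seed=3))
    return inst, mask


@pytest.fixture(scope="session")
def grass_blade():
    inst, mask = fx.make_instance(fx.FixtureSpec(archetype="grass_blade", size=64, seed=3))
    return inst, mask


@pytest.fixture(scope="session")
def small_pool():
    return fx.make_pool(ip_size=5, size=48, seed=0)


def solid_square(side: int, color=(60, 150, 50), label="cotton"):
    """Fully opaque square instance — handy for exact-arithmetic cases."""
    from weedsynth.clipper import PlantInstance

    rgba = np.zeros((side, side, 4), dtype=np.uint8)
    rgba[..., 0], rgba[..., 1], rgba[..., 2] = color
    rgba[..., 3] = 255
    return PlantInstance(raster=rgba, class_label=label, source_id=f"square{side}")
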