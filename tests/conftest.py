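import numpy as np
import pytest

from replipat import RoiPolygon, SceneSpec, gen_roi


@pytest.fixture
def square_um2() -> RoiPolygon:
    """1 µm² axis-aligned square (side 1000 nm) with one corner at the origin."""
    return RoiPolygon(((0, 0), (1000, 0), (1000, 1000), (0, 1000)), kind="other",
                      id="sq1")


@pytest.fixture
def az_square() -> RoiPolygon:
    return RoiPolygon(((0, 0), (500, 0), (500, 500), (0, 500)), kind="AZ",
                      id="az1")


@pytest.fixture
def disk_4um2() -> RoiPolygon:
    return gen_roi(SceneSpec(roi_shape="disk", roi_area=4.0, seed=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
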