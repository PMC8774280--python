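import numpy as np
import pytest

from vsatnet import synthetic as syn
from vsatnet.paradigm import ParadigmSpec


@pytest.fixture(scope="session")
def default_paradigm() -> ParadigmSpec:
    return ParadigmSpec()


@pytest.fixture(scope="session")
def toy_atlas():
    """Default-sized atlas: 6 WM tracts + 10 GM regions on 24x24x16."""
    return syn.make_toy_atlas((24, 24, 16), 6, 10, seed=1)


@pytest.fixture(scope="session")
def small_atlas():
    """Small parcels on a small grid, for fast volume-level tests."""
    return syn.make_toy_atlas(
        (12, 12, 8), 2, 2, seed=2, min_parcel_voxels=24
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
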