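import numpy as np
import pytest

from crowdcount import MosaicSpec, RetirementPolicy, VolunteerModel, tile_mosaic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_mosaic():
    """2100 x 1400 px island with a central rectangular content region."""
    mask = np.zeros((1400, 2100), dtype=bool)
    mask[200:1200, 300:1800] = True
    return MosaicSpec(width=2100, height=1400, flight_id="f1", content_mask=mask)


@pytest.fixture
def small_tiles(small_mosaic):
    return tile_mosaic(small_mosaic, 700)


@pytest.fixture
def noise_free_model():
    return VolunteerModel(p_detect=1.0, fp_rate=0.0, count_jitter=0.0, seed=7)


@pytest.fixture
def default_policy():
    return RetirementPolicy()
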