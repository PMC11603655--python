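import numpy as np
import pytest

from cortexscope.regions import synthetic_atlas
from cortexscope.synth import SynthConfig, generate_region_traces


@pytest.fixture(scope="session")
def atlas_small():
    """Compact atlas (one 2x7-pixel strip per subdivision) for movie tests."""
    return synthetic_atlas((68, 20), border=2)


@pytest.fixture(scope="session")
def short_cfg():
    """Default generative parameters on a 60-s session, small rendering."""
    return SynthConfig(session_s=60.0, movie_shape=(68, 20))


@pytest.fixture(scope="session")
def saline_session(short_cfg):
    return generate_region_traces(short_cfg, "saline", np.random.default_rng(11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
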