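import numpy as np
import pytest

from tauseed.atlas import default_atlas
from tauseed.connectome import build_connectome
from tauseed.synthetic import get_preset, synth_atlas, synth_connectome


@pytest.fixture(scope="session")
def atlas84():
    return default_atlas()


@pytest.fixture(scope="session")
def part_config():
    return get_preset("PART_like", rng_seed=1)


@pytest.fixture(scope="session")
def conn84(atlas84, part_config):
    return synth_connectome(part_config, atlas84)


@pytest.fixture(scope="session")
def atlas5():
    return synth_atlas(5)


@pytest.fixture(scope="session")
def conn5(atlas5):
    rng = np.random.default_rng(11)
    M = rng.uniform(0.3, 1.0, size=(5, 5))
    return build_connectome([M], cutoff=0.01, atlas=atlas5)


@pytest.fixture(scope="session")
def atlas2():
    return synth_atlas(2)
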