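import numpy as np
import pytest

from cemcurate import SynthConfig, make_informative_patch


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig()


@pytest.fixture(scope="session")
def informative_patch(synth_cfg):
    """One deterministic informative patch with its ground-truth masks."""
    return make_informative_patch(synth_cfg, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
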