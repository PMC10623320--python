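import numpy as np
import pytest
from hypothesis import settings

from rootedit.core import Amplicon
from rootedit.simulate import RepairSpectrumConfig, make_amplicon, pick_guide

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def amplicon():
    return make_amplicon(300, 0.45, seed=7)


@pytest.fixture(scope="session")
def site(amplicon):
    return pick_guide(amplicon)


@pytest.fixture(scope="session")
def default_config():
    return RepairSpectrumConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_amplicon():
    # 23-nt single forward guide site: 20 Gs + AGG PAM
    return Amplicon("toy", "G" * 20 + "AGG", 0, 21)
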