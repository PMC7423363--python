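import pytest

from msh import (
    KineticParams,
    ReactorConfig,
    default_kinetics,
    make_toy_models,
)
from msh.synth import DEXTRAN_FEED_MM


@pytest.fixture(scope="session")
def toy_models():
    aerobe, anaerobe = make_toy_models()
    return {"aerobe": aerobe, "anaerobe": anaerobe}


@pytest.fixture(scope="session")
def kinetics() -> KineticParams:
    return default_kinetics()


@pytest.fixture()
def reactor_config() -> ReactorConfig:
    return ReactorConfig(s_feed={"glc_e": 0.0, "dex_e": DEXTRAN_FEED_MM})
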