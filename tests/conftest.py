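import pytest

from bayestime import ObserverParams, make_design


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture
def params():
    return ObserverParams()
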