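import pytest

from intron_order.synthetic_data import gapc_like, rbcs_like, tuba_like


@pytest.fixture(scope="session")
def tuba():
    return tuba_like()


@pytest.fixture(scope="session")
def gapc():
    return gapc_like()


@pytest.fixture(scope="session")
def rbcs():
    return rbcs_like()
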