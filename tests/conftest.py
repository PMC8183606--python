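import pytest

from cahscreen import preset


@pytest.fixture(scope="session")
def base_params():
    return preset("base")


@pytest.fixture(scope="session")
def best_params():
    return preset("best")


@pytest.fixture(scope="session")
def worst_params():
    return preset("worst")
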