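import pytest

from symbio import build_scenario, build_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return build_taxonomy()


@pytest.fixture()
def scenario1():
    return build_scenario(1)


@pytest.fixture()
def scenario2():
    return build_scenario(2)


@pytest.fixture()
def scenario3():
    return build_scenario(3)
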