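import pytest

from pl7loop import (
    alyv_standin,
    pyaly_standin,
    standin_templates,
    load_reference_set,
)


@pytest.fixture(scope="session")
def pyaly():
    return pyaly_standin()


@pytest.fixture(scope="session")
def alyv():
    return alyv_standin()


@pytest.fixture(scope="session")
def templates():
    return standin_templates()


@pytest.fixture(scope="session")
def reference_set():
    return load_reference_set()
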