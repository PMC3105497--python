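import pytest

from flowsynth import workbench


@pytest.fixture(scope="session")
def manual_domain():
    return workbench.manual_hmmer_domain()


@pytest.fixture(scope="session")
def auto_domain():
    return workbench.auto_hmmer_domain()


@pytest.fixture(scope="session")
def example3_domain():
    return workbench.example3_domain()


@pytest.fixture()
def type_taxonomy(manual_domain):
    return manual_domain.type_taxonomy


@pytest.fixture()
def service_taxonomy(manual_domain):
    return manual_domain.service_taxonomy
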