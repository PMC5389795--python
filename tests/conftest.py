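import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_case():
    from mcrc_cea import load_base_case

    return load_base_case()


@pytest.fixture()
def scenario(base_case):
    """A mutable copy of the bundled base case."""
    return base_case.copy()
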