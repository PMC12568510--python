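import pytest
from hypothesis import settings

from hfpheno.algorithms import builtin_registry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from hfpheno.records import default_codeset


@pytest.fixture(scope="session")
def codeset():
    return default_codeset()


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()
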