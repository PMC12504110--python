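import pytest
from hypothesis import settings

from climvalue import load_reference_estimates, reference_vsl_parameters

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_records():
    return load_reference_estimates()


@pytest.fixture(scope="session")
def vsl_params():
    return reference_vsl_parameters()
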