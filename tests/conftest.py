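import pytest

from spfam.config import PipelineConfig
from spfam.reference import load_reference


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()
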