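import pytest

from ricegas import load_params


@pytest.fixture(scope="session")
def params():
    """Default study parameters."""
    return load_params()
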