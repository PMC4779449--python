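import pytest

from soilstruct.datasets import load_study_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Bundled four-farm study data."""
    return load_study_fixtures("all")
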