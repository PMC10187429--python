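import pytest

from cellprompt import MockBackend, TissueContext, fixtures


@pytest.fixture
def breast_markers():
    return fixtures.breast_marker_set()


@pytest.fixture
def mock_dictionary(breast_markers):
    return fixtures.mock_dictionary_from(breast_markers)


@pytest.fixture
def mock_backend(mock_dictionary):
    return MockBackend(mock_dictionary)


@pytest.fixture
def context():
    return TissueContext(species="human", tissue="breast")
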