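import pytest
from hypothesis import settings

from mitolineage import (
    default_classification_weights,
    load_packaged_tree,
    load_reference,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def tree():
    return load_packaged_tree()


@pytest.fixture(scope="session")
def weights():
    return default_classification_weights()
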