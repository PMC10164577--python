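import pytest

from strandfold import synthgen


@pytest.fixture(scope="session")
def refs():
    """Small k-mer-disjoint reference set shared across mapping tests."""
    return synthgen.gen_references(seed=1)
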