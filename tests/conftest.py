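import pytest
from hypothesis import settings

from isomirseq.pipeline import default_synthetic_references

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def refs():
    """Two synthetic hairpins (three arms) with 10-nt genomic flanks."""
    return default_synthetic_references(0)


@pytest.fixture(scope="session")
def hairpins(refs):
    return refs[0]


@pytest.fixture(scope="session")
def arms(refs):
    return refs[1]
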