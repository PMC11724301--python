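import pytest

from breakins import build_locus, default_genome


@pytest.fixture(scope="session")
def locus():
    return build_locus()


@pytest.fixture(scope="session")
def genome():
    return default_genome()
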