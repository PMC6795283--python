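import pytest

from scampr import (build_design, build_gene_fixture, bdcesa_alignment)


@pytest.fixture(scope="session")
def gene():
    return build_gene_fixture(seed=1)


@pytest.fixture(scope="session")
def default_design():
    """The screen's layout: 3840 plants, 8x pools, 20x24 grid."""
    return build_design(3840, 8, 20, 24)


@pytest.fixture(scope="session")
def small_design():
    """Reduced layout for Monte-Carlo suites: 128 plants, 4x4 grid."""
    return build_design(128, 8, 4, 4)


@pytest.fixture(scope="session")
def table1_alignment():
    names, seqs = bdcesa_alignment()
    return names, seqs
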