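import pytest

from dup15q import load_table1_counts, load_table3_inheritance


@pytest.fixture(scope="session")
def table1():
    """Published per-study carrier counts (all three cohort classes)."""
    return load_table1_counts()


@pytest.fixture(scope="session")
def table3():
    """Published de novo / inherited tallies by parental origin."""
    return load_table3_inheritance()
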