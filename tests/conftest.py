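import pytest

from poolmap import synthetic as syn


@pytest.fixture(scope="session")
def default_panel():
    """Default phased panel: 186 chromosomes, four majors covering ~77%."""
    return syn.gen_haplotype_panel()


@pytest.fixture(scope="session")
def default_cohort(default_panel):
    """Default retrospective cohort: 127 cases / 135 controls."""
    return syn.gen_cohort(default_panel)


@pytest.fixture(scope="session")
def major_groups(default_panel):
    from poolmap.haplotypes import cluster_major_haplotypes

    groups, coverage = cluster_major_haplotypes(default_panel)
    return [g for g in groups if g.is_major], coverage
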