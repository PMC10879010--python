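import pytest

from chromoshard import workflows


@pytest.fixture(scope="session")
def study():
    """The standard study conditions: 1-Mb diploid chromosome, SNP rate 1e-3,
    100 chromothripsis breakpoints over the whole chromosome, 40% fragment
    loss, 12-kb reads at 20x per copy with 1% substitution errors."""
    return workflows.simulate_study(seed=1)


@pytest.fixture(scope="session")
def recovery(study):
    """Full haplotype-recovery run (SV validation through read partition)."""
    return workflows.recover_haplotypes(study, seed=1)


@pytest.fixture(scope="session")
def small_genome():
    from chromoshard import simulate

    return simulate.build_diploid_genome(1, 100_000, 1e-3, seed=5)
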