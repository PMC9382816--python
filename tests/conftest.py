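"""Shared fixtures: one small synthetic community and a couple of
genomes, generated once per session and reused across test modules."""

import pytest

from viromine import recruit as rc, simulate as sim


@pytest.fixture(scope="session")
def genome20k():
    """A 20-kb circular genome with 20 planted genes at 35% GC."""
    return sim.make_genome(20_000, 0.35, 20, seed=1, genome_id="g20k")


@pytest.fixture(scope="session")
def small_spec():
    return sim.CommunitySpec(
        phages=[
            sim.PhageSpec("p1", 12_000, 0.35, 0.5),
            sim.PhageSpec("p2", 15_000, 0.45, 0.3),
            sim.PhageSpec("p3", 10_000, 0.50, 0.2),
        ],
        n_reads=3_000,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_community(small_spec):
    """Three-phage community, 3,000 reads, 1% errors, 20% decoy reads."""
    return sim.make_community(
        small_spec, genome_seed=100, n_decoy_genomes=2, decoy_genome_length=12_000
    )


@pytest.fixture(scope="session")
def small_recruitment(small_community):
    com = small_community
    return rc.recruit_reads(com.reads, com.refs, com.decoy_proteins)


@pytest.fixture(scope="session")
def donor_phage():
    return sim.make_genome(40_000, 0.4, 37, seed=9, genome_id="donor").genome


@pytest.fixture(scope="session")
def crispr_host(donor_phage):
    """Host with a planted 14-repeat / 13-spacer array; spacers 7, 9,
    11, 13 copied exactly from the donor and spacer 12 with one
    mismatch."""
    return sim.make_crispr_host(donor_phage, seed=4)
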