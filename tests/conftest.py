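import pytest

from psyllomito.simulate import (GenomeSpec, generate_genome, evolve_panel,
                                 psyllid_diversity_spec,
                                 psyllid_phylogeny_spec)


@pytest.fixture(scope="session")
def genome():
    """The default synthetic psyllid mitogenome."""
    return generate_genome(GenomeSpec(seed=1))


@pytest.fixture(scope="session")
def diversity_panel(genome):
    """Four taxa evolved on a star with the per-gene diversity profile."""
    return evolve_panel(genome, psyllid_diversity_spec(seed=7))


@pytest.fixture(scope="session")
def phylo_panel(genome):
    """Six taxa evolved along the two-family + outgroups topology."""
    return evolve_panel(genome, psyllid_phylogeny_spec(seed=11))


def gene_alignment(panel, gene):
    from psyllomito.alignment import MultipleAlignment
    return MultipleAlignment(
        [p.metadata["accession"] for p in panel],
        [p.get(gene).sense_sequence(p.sequence) for p in panel])
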