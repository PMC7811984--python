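import pytest

from ampliclade.primers import codhech_primer_sets
from ampliclade.synth_fixtures import FamilySpec, simulate_gene_family


@pytest.fixture(scope="session")
def published_sets():
    return codhech_primer_sets()


@pytest.fixture(scope="session")
def default_family():
    """The four-clade reference family carrying all six published primer sets."""
    return simulate_gene_family(FamilySpec(seed=1))


@pytest.fixture(scope="session")
def single_clade_family(published_sets):
    """A small one-clade family for alignment-heavy tests."""
    ps = next(s for s in published_sets if s.name == "F4c1_p1")
    spec = FamilySpec(
        n_genera=1,
        species_per_genus=4,
        strains_per_species=2,
        gene_len=900,
        primer_sets=(ps,),
        n_edge_per_genus=0,
        seed=11,
    )
    return simulate_gene_family(spec), ps
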