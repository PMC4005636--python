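import pytest

from mytaxa import simulate as sim
from mytaxa.pipeline import BuildConfig, build_weight_db


@pytest.fixture(scope="session")
def tiny_reference():
    """2 phyla x 2 genera x 2 species x 2 genomes, 10 families, no HGT."""
    tax = sim.TaxonomySpec(
        n_phyla=2, genera_per_phylum=2, species_per_genus=2, genomes_per_species=2
    )
    fam = sim.GeneFamilySpec(n_families=10, hgt_rate=0.0)
    return sim.simulate_reference_set(tax, fam, seed=11)


@pytest.fixture(scope="session")
def tiny_build(tiny_reference):
    matches = sim.reference_match_table(tiny_reference)
    return build_weight_db(
        tiny_reference.genes, matches, tiny_reference.taxonomy, BuildConfig()
    )


@pytest.fixture(scope="session")
def tiny_db(tiny_build):
    return tiny_build.db


class FakeWeightDB:
    """Dict-backed weight DB implementing the classifier lookup protocol."""

    def __init__(self, gene_to_cluster, gene_to_genome, weights):
        self.gene_to_cluster = gene_to_cluster
        self.gene_to_genome = gene_to_genome
        self.weights = weights

    def lookup(self, accession):
        if accession not in self.gene_to_cluster:
            return None
        return self.gene_to_cluster[accession], self.gene_to_genome[accession]

    def rank_weights(self, cluster_id, rank):
        return self.weights.get((cluster_id, rank))


@pytest.fixture
def fake_db_factory():
    return FakeWeightDB
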