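import pytest

import phylotracks as pt
from phylotracks.fixtures import FixtureSpec, synth_genome, synth_tree_and_sequences


@pytest.fixture(scope="session")
def genome_fixture():
    """A small planted genome: 2 operons (3+2 genes), 12 genes, 3 queries."""
    return synth_genome(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def annotation(genome_fixture):
    return pt.read_gff3(genome_fixture.gff3)


@pytest.fixture(scope="session")
def hits(genome_fixture):
    return pt.read_hits_tsv(genome_fixture.hits_tsv)


@pytest.fixture(scope="session")
def architectures(hits):
    return pt.build_architectures(hits, pt.DomainsConfig())


@pytest.fixture(scope="session")
def tree_fixture():
    """A 6-leaf random tree, its evolved sequences and additive matrix."""
    return synth_tree_and_sequences(FixtureSpec(seed=7, tree_leaves=6))


@pytest.fixture(scope="session")
def neighborhoods_result(genome_fixture, annotation, hits):
    store = {r.id: r for r in pt.read_fasta(genome_fixture.fasta)}
    ids = "\n".join(genome_fixture.truth["query_proteins"])
    return pt.run_neighborhoods_pipeline(
        ids, annotation, hits, pt.NeighborhoodsConfig(), sequence_store=store
    )
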