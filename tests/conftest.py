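import pytest

from famevol import phylo, simulate


@pytest.fixture(scope="session")
def species_tree():
    return simulate.default_species_tree()


@pytest.fixture(scope="session")
def burst_dataset(species_tree):
    """Five deeply separated ancestral copies with a recent duplication
    burst confined to the terminal branches."""
    cfg = simulate.SimConfig(
        n_ancestral_copies=5,
        birth_rate=0.0,
        death_rate=0.0,
        omega=0.2,
        codon_length=120,
        recent_burst=(0.005, 60.0),
        seed=11,
    )
    genes, truth = simulate.simulate_dataset(species_tree, cfg)
    return genes, truth, cfg


@pytest.fixture(scope="session")
def burst_partition(burst_dataset):
    genes, truth, _ = burst_dataset
    aln = phylo.CodonAlignment.from_equal_length_cds(genes)
    tree = phylo.nj_tree(aln, n_bootstrap=100, seed=5)
    species_of = {g.gene_id: g.species for g in genes}
    part = phylo.partition_clades(tree, species_of, outgroup="Fves", min_ingroup_species=5)
    return part, tree, species_of, aln
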